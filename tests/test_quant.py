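"""dNSAF quantification: distribution rule, normalization, bdNSAF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from _oracles import distribute_counts_loop
from apmskit.io import PeptideEvidence, ProteinDatabase, ProteinRecord
from apmskit.quant import (
    EmptyRunError,
    QuantifiedRun,
    compute_bdnsaf,
    compute_dnsaf,
    distribute_shared_counts,
    quantify_run,
)
from conftest import make_evidence


class TestDistributeSharedCounts:
    def test_proportional_split(self):
        # A has 6 unique counts, B has 2; shared peptide with 4 counts
        # splits 3:1, giving distributed totals 9 and 3.
        ev = make_evidence(
            "r1",
            ("AAAK", 6, ["A"]),
            ("CCCK", 2, ["B"]),
            ("DDDK", 4, ["A", "B"]),
        )
        df = distribute_shared_counts(ev)
        assert df.loc["A", "dSpC"] == pytest.approx(9.0)
        assert df.loc["B", "dSpC"] == pytest.approx(3.0)

    def test_no_shared_is_identity(self):
        ev = make_evidence("r1", ("AAAK", 5, ["A"]), ("CCCK", 3, ["B"]))
        df = distribute_shared_counts(ev)
        assert df["dSpC"].tolist() == [5.0, 3.0]
        assert (df["sSpC_assigned"] == 0).all()

    def test_all_zero_unique_owners_split_equally(self):
        ev = make_evidence("r1", ("DDDK", 4, ["A", "B"]))
        df = distribute_shared_counts(ev)
        assert df.loc["A", "dSpC"] == pytest.approx(2.0)
        assert df.loc["B", "dSpC"] == pytest.approx(2.0)

    def test_mixed_runs_rejected(self):
        ev = make_evidence("r1", ("AAAK", 1, ["A"])) + make_evidence(
            "r2", ("AAAK", 1, ["A"])
        )
        with pytest.raises(ValueError, match="one run at a time"):
            distribute_shared_counts(ev)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 10),
                st.lists(st.sampled_from("ABCDEF"), min_size=1, max_size=4,
                         unique=True),
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_per_peptide_loop_oracle_and_conserves_counts(self, data):
        ev = [
            PeptideEvidence("r1", f"PEP{i}K", count, frozenset(owners))
            for i, (count, owners) in enumerate(data)
        ]
        df = distribute_shared_counts(ev)
        oracle = distribute_counts_loop(
            [(count, tuple(sorted(owners))) for count, owners in data]
        )
        for acc, (u, s) in oracle.items():
            assert df.loc[acc, "uSpC"] == pytest.approx(u)
            assert df.loc[acc, "sSpC_assigned"] == pytest.approx(s, abs=1e-9)
        total_raw = sum(count for count, _ in data)
        assert df["dSpC"].sum() == pytest.approx(total_raw, abs=1e-9)
        assert (df["dSpC"] >= df["uSpC"] - 1e-12).all()

    def test_monotone_in_unique_counts(self):
        base = make_evidence(
            "r1", ("AAAK", 2, ["A"]), ("CCCK", 6, ["B"]), ("DDDK", 10, ["A", "B"])
        )
        bumped = make_evidence(
            "r1", ("AAAK", 3, ["A"]), ("CCCK", 6, ["B"]), ("DDDK", 10, ["A", "B"])
        )
        d0 = distribute_shared_counts(base)
        d1 = distribute_shared_counts(bumped)
        assert d1.loc["A", "dSpC"] >= d0.loc["A", "dSpC"]


class TestComputeDnsaf:
    def test_single_protein_is_one(self):
        out = compute_dnsaf({"A": 4.0}, {"A": 100})
        assert out["A"] == pytest.approx(1.0)

    def test_length_normalization(self):
        # 9 counts over 300 residues equals 3 counts over 100 residues
        out = compute_dnsaf({"A": 9.0, "B": 3.0}, {"A": 300, "B": 100})
        assert out["A"] == pytest.approx(0.5)
        assert out["B"] == pytest.approx(0.5)

    def test_sum_is_one_on_random_runs(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            dspc = {f"P{i}": float(rng.integers(0, 30)) for i in range(n)}
            if sum(dspc.values()) == 0:
                dspc["P0"] = 1.0
            lengths = {f"P{i}": int(rng.integers(50, 900)) for i in range(n)}
            out = compute_dnsaf(dspc, lengths)
            assert out.sum() == pytest.approx(1.0, abs=1e-9)
            assert ((out >= 0) & (out <= 1)).all()

    def test_empty_run_errors(self):
        with pytest.raises(EmptyRunError):
            compute_dnsaf({"A": 0.0}, {"A": 100})


class TestBdnsaf:
    def _run(self, dnsaf_map):
        table = pd.DataFrame({"dNSAF": pd.Series(dnsaf_map)})
        return QuantifiedRun("r1", table)

    def test_hand_ratio(self):
        run = self._run({"bait": 0.04, "prey": 0.02})
        assert compute_bdnsaf(run, "bait", "prey") == pytest.approx(0.5)

    def test_equal_is_one_and_absent_is_zero(self):
        run = self._run({"bait": 0.04, "prey": 0.04})
        assert compute_bdnsaf(run, "bait", "prey") == pytest.approx(1.0)
        assert compute_bdnsaf(run, "bait", "ghost") == 0.0

    def test_undetected_bait_errors(self):
        run = self._run({"prey": 0.02})
        with pytest.raises(ValueError, match="bdNSAF undefined"):
            compute_bdnsaf(run, "bait", "prey")


def test_paralog_dnsaf_tracks_planted_abundance_ratio(rng):
    """Two paralogs sharing half their peptides: across 100 simulated runs
    the dNSAF ratio rank-tracks the planted abundance ratio (Spearman >= 0.9)."""
    n_pep = 12
    shared = [f"SH{i}K" for i in range(n_pep // 2)]
    only_a = [f"AA{i}K" for i in range(n_pep // 2)]
    only_b = [f"BB{i}K" for i in range(n_pep // 2)]
    proteins = ProteinDatabase(
        [
            ProteinRecord("parA", "".join(shared + only_a)),
            ProteinRecord("parB", "".join(shared + only_b)),
        ]
    )
    planted, observed = [], []
    for run_idx in range(100):
        ratio = float(np.exp(rng.uniform(-1.5, 1.5)))
        abundance = {"parA": 8.0 * ratio, "parB": 8.0}
        ev = []
        for pep in shared:
            lam = abundance["parA"] + abundance["parB"]
            c = int(rng.poisson(lam))
            if c:
                ev.append(PeptideEvidence(f"r{run_idx}", pep, c,
                                          frozenset({"parA", "parB"})))
        for pep, owner in [(p, "parA") for p in only_a] + [(p, "parB") for p in only_b]:
            c = int(rng.poisson(abundance[owner]))
            if c:
                ev.append(PeptideEvidence(f"r{run_idx}", pep, c, frozenset({owner})))
        q = quantify_run(ev, proteins)
        if q.dnsaf("parB") > 0:
            planted.append(ratio)
            observed.append(q.dnsaf("parA") / q.dnsaf("parB"))
    rho = spearmanr(planted, observed).statistic
    assert rho >= 0.9
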