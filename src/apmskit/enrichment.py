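"""Prevalence pre-filter and Bayesian Poisson enrichment scoring.

The model is a per-prey Poisson generalized linear model on spectral counts:

    y_ij ~ Poisson(mu_ij),   log mu_ij = alpha_i + o_j + beta_i * x_j

where x_j is 1 for bait runs and 0 for pooled negative-control runs and o_j
is a known log-offset (run-depth normalization; any per-prey constant such
as log protein length is absorbed by alpha_i).  Weakly informative normal
priors are placed on alpha (sd 10) and beta (sd 3, i.e. fold changes beyond
~e^9 are a priori implausible).  The posterior is sampled with
Metropolis-within-Gibbs random-walk updates whose step sizes adapt toward a
0.44 acceptance rate during burn-in and are frozen afterwards, so the
retained chain is a valid fixed-kernel sampler.  The reported statistics are

    log2fc = E[beta] / ln 2          (posterior-mean group effect, log2 scale)
    z_stat = E[beta] / SD[beta]      (posterior mean over posterior sd)

and a prey is called enriched when z_stat >= z_min and log2fc >= fc_min
(defaults 3 and 2, both inclusive).

The sampler is vectorized across preys: all chains advance in lockstep with
per-prey acceptance, which makes scoring hundreds of preys with a
2000-iteration burn-in and 10,000 retained draws a sub-second operation.
Given identical data and seed the results are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from apmskit.io import StudyDesign

LN2 = math.log(2.0)

_ALPHA_PRIOR_SD = 10.0
_BETA_PRIOR_SD = 3.0


@dataclass(frozen=True)
class McmcSettings:
    """Sampler configuration: draws discarded, draws retained, RNG seed."""

    burn_in: int = 2000
    iterations: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def prevalence_filter(
    counts: pd.DataFrame,
    design: StudyDesign,
) -> list[str]:
    """Preys retained for scoring: detected (count > 0) in at least half of
    some bait's replicates, i.e. detections >= ceil(n_replicates / 2).

    ``counts`` is a protein x run matrix; runs absent from the matrix count
    as non-detections.
    """
    retained = []
    per_bait = {
        bait: [r for r in design.runs_for_bait(bait) if r in counts.columns]
        for bait in design.baits
    }
    for prey in counts.index:
        for bait in design.baits:
            n = design.n_replicates(bait)
            if n == 0:
                continue
            detections = int((counts.loc[prey, per_bait[bait]] > 0).sum()) if per_bait[bait] else 0
            if detections >= math.ceil(n / 2):
                retained.append(prey)
                break
    return retained


def fit_poisson_enrichment(
    bait_counts: np.ndarray,
    control_counts: np.ndarray,
    settings: McmcSettings | None = None,
    bait_offsets: np.ndarray | None = None,
    control_offsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit the Poisson group-effect model for one or many preys.

    Parameters
    ----------
    bait_counts, control_counts:
        Integer arrays of shape ``(n_preys, n_runs)`` (a single 1-D vector is
        treated as one prey).  Rows are preys, columns are runs.
    bait_offsets, control_offsets:
        Optional per-run log-offsets (e.g. log of run total spectral counts
        relative to their mean); defaults to zero.

    Returns a DataFrame with one row per prey: ``log2fc``, ``z_stat``,
    ``post_sd_log2`` (posterior sd of the effect on the log2 scale) and
    ``skipped`` (True for all-zero preys, which are never scored; their
    statistics are NaN).
    """
    settings = settings or McmcSettings()
    yb = np.atleast_2d(np.asarray(bait_counts, dtype=float))
    yc = np.atleast_2d(np.asarray(control_counts, dtype=float))
    if yb.shape[0] != yc.shape[0]:
        raise ValueError("bait and control count arrays disagree on prey count")
    if yb.shape[1] < 1 or yc.shape[1] < 1:
        raise ValueError("need at least one run per group")
    if (yb < 0).any() or (yc < 0).any():
        raise ValueError("spectral counts must be non-negative")

    ob = np.zeros(yb.shape[1]) if bait_offsets is None else np.asarray(bait_offsets, float)
    oc = np.zeros(yc.shape[1]) if control_offsets is None else np.asarray(control_offsets, float)
    T1 = float(np.exp(ob).sum())  # total bait exposure
    T0 = float(np.exp(oc).sum())  # total control exposure

    R = yb.shape[0]
    S_yb = yb.sum(axis=1)
    S_yc = yc.sum(axis=1)
    S_y = S_yb + S_yc
    active = S_y > 0

    log2fc = np.full(R, np.nan)
    z_stat = np.full(R, np.nan)
    post_sd = np.full(R, np.nan)

    if active.any():
        mean_b, sd_b = _sample_beta(
            S_y[active], S_yb[active], T0, T1, settings
        )
        log2fc[active] = mean_b / LN2
        post_sd[active] = sd_b / LN2
        z_stat[active] = mean_b / sd_b

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "z_stat": z_stat,
            "post_sd_log2": post_sd,
            "skipped": ~active,
        }
    )


def _sample_beta(
    S_y: np.ndarray,
    S_yb: np.ndarray,
    T0: float,
    T1: float,
    settings: McmcSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Metropolis-within-Gibbs for (alpha, beta) across preys.

    The Poisson log-likelihood depends on the data only through the
    sufficient statistics S_y (total counts), S_yb (bait-group counts) and
    the group exposures T0, T1, which makes each update O(1) per prey.
    Returns the posterior mean and sd of beta (natural-log scale).
    """
    rng = np.random.default_rng(settings.seed)
    R = S_y.shape[0]

    # moment-based initialization, offset-aware
    rate_c = (S_y - S_yb + 0.5) / T0
    rate_b = (S_yb + 0.5) / T1
    alpha = np.log(rate_c)
    beta = np.log(rate_b) - np.log(rate_c)

    step_a = np.full(R, 0.5)
    step_b = np.full(R, 0.5)
    target = 0.44  # canonical optimum for one-dimensional random-walk updates

    sum_b = np.zeros(R)
    sum_b2 = np.zeros(R)

    n_total = settings.burn_in + settings.iterations
    ea = np.exp(alpha)
    eb = np.exp(beta)
    va_prior = _ALPHA_PRIOR_SD ** 2
    vb_prior = _BETA_PRIOR_SD ** 2

    for t in range(n_total):
        adapting = t < settings.burn_in

        # --- alpha update ---------------------------------------------
        prop = alpha + step_a * rng.standard_normal(R)
        e_prop = np.exp(prop)
        delta = (
            S_y * (prop - alpha)
            - (e_prop - ea) * (T0 + T1 * eb)
            - (prop ** 2 - alpha ** 2) / (2 * va_prior)
        )
        accept = np.log(rng.uniform(size=R)) < delta
        alpha = np.where(accept, prop, alpha)
        ea = np.where(accept, e_prop, ea)
        if adapting:
            acc_prob = np.exp(np.minimum(delta, 0.0))
            step_a *= np.exp((acc_prob - target) / math.sqrt(t + 1.0))

        # --- beta update ----------------------------------------------
        prop = beta + step_b * rng.standard_normal(R)
        e_prop = np.exp(prop)
        delta = (
            S_yb * (prop - beta)
            - ea * T1 * (e_prop - eb)
            - (prop ** 2 - beta ** 2) / (2 * vb_prior)
        )
        accept = np.log(rng.uniform(size=R)) < delta
        beta = np.where(accept, prop, beta)
        eb = np.where(accept, e_prop, eb)
        if adapting:
            acc_prob = np.exp(np.minimum(delta, 0.0))
            step_b *= np.exp((acc_prob - target) / math.sqrt(t + 1.0))

        if not adapting:
            sum_b += beta
            sum_b2 += beta * beta

    n = settings.iterations
    mean_b = sum_b / n
    var_b = np.maximum(sum_b2 / n - mean_b ** 2, 1e-300)
    return mean_b, np.sqrt(var_b)


def call_enriched(
    results: pd.DataFrame,
    z_min: float = 3.0,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Apply the inclusive enrichment thresholds (z_stat >= z_min AND
    log2fc >= fc_min); returns a copy with an ``enriched`` boolean column."""
    out = results.copy()
    out["enriched"] = (
        (out["z_stat"] >= z_min) & (out["log2fc"] >= fc_min)
    ).fillna(False)
    if "skipped" in out.columns:
        out.loc[out["skipped"], "enriched"] = False
    return out


def score_bait(
    counts: pd.DataFrame,
    design: StudyDesign,
    bait_id: str,
    settings: McmcSettings | None = None,
    offsets: Mapping[str, float] | None = None,
    preys: Sequence[str] | None = None,
    exclude_bait: bool = True,
) -> pd.DataFrame:
    """Score one bait's runs against the pooled negative-control runs.

    ``counts`` is a protein x run matrix of (integer) spectral counts;
    ``offsets`` optionally maps run_id to a log-offset.  The bait protein
    itself is excluded from scoring by default (its enrichment is a tagging
    artifact, not an interaction).
    """
    design.require_controls()
    bait_runs = [r for r in design.runs_for_bait(bait_id) if r in counts.columns]
    control_runs = [r for r in design.control_runs if r in counts.columns]
    if not bait_runs:
        raise ValueError(f"no runs with counts for bait {bait_id!r}")
    if not control_runs:
        raise ValueError("no control runs with counts")

    prey_index = list(counts.index if preys is None else preys)
    if exclude_bait:
        prey_index = [p for p in prey_index if p != bait_id]

    yb = counts.loc[prey_index, bait_runs].to_numpy(dtype=float)
    yc = counts.loc[prey_index, control_runs].to_numpy(dtype=float)
    ob = np.array([offsets.get(r, 0.0) for r in bait_runs]) if offsets else None
    oc = np.array([offsets.get(r, 0.0) for r in control_runs]) if offsets else None

    res = fit_poisson_enrichment(yb, yc, settings, ob, oc)
    res.insert(0, "prey_id", prey_index)
    res.insert(0, "bait_id", bait_id)
    res["n_bait_runs_detected"] = (yb > 0).sum(axis=1)
    res["n_control_runs_detected"] = (yc > 0).sum(axis=1)
    return res


def enrich_count_matrix(
    counts: pd.DataFrame,
    design: StudyDesign,
    settings: McmcSettings | None = None,
    z_min: float = 3.0,
    fc_min: float = 2.0,
    offsets: Mapping[str, float] | None = None,
    apply_prevalence_filter: bool = True,
) -> pd.DataFrame:
    """Full enrichment chain on a spectral-count matrix: prevalence filter,
    per-bait Poisson scoring against pooled controls, threshold calls.

    Each bait is scored with a seed derived deterministically from
    ``settings.seed`` and the bait's position in the design, so baits have
    independent chains yet the whole analysis is reproducible.
    """
    settings = settings or McmcSettings()
    retained = (
        prevalence_filter(counts, design) if apply_prevalence_filter else list(counts.index)
    )
    frames = []
    for i, bait in enumerate(design.baits):
        bait_settings = McmcSettings(
            settings.burn_in, settings.iterations, (settings.seed + 7919 * i) % (2 ** 31)
        )
        res = score_bait(counts, design, bait, bait_settings, offsets, preys=retained)
        frames.append(call_enriched(res, z_min, fc_min))
    return pd.concat(frames, ignore_index=True)


def enriched_sets(results: pd.DataFrame) -> dict[str, set[str]]:
    """Per-bait sets of enriched prey accessions from a scored table."""
    out: dict[str, set[str]] = {}
    for bait, grp in results.groupby("bait_id"):
        out[str(bait)] = set(grp.loc[grp["enriched"], "prey_id"])
    return out
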