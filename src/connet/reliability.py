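"""Robustness of node strength to incomplete electrode sampling.

A fraction of channels is removed at random, node strengths of the retained
channels are recomputed, and reliability is summarized as

    R = sigma_T / (sigma_T + sigma_E)

where sigma_E (error variance) is the across-iteration variance of a
contact's strength averaged over contacts, and sigma_T (true variance) is
the across-contact variance averaged over iterations.  R is 1 for a measure
whose node ranking is untouched by subsampling and 0 when subsampling noise
swamps the across-contact signal.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .connectivity import ConnectivityNetwork

logger = logging.getLogger("connet")

FRACTIONS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class ReliabilityPoint:
    fraction: float
    R: float
    sigma_T: float
    sigma_E: float
    n_iter: int


@dataclass
class ReliabilityCurve:
    pipeline: object
    points: list[ReliabilityPoint] = field(default_factory=list)

    @property
    def fractions(self) -> list[float]:
        return [p.fraction for p in self.points]

    @property
    def R(self) -> list[float]:
        return [p.R for p in self.points]


def node_strength(net: ConnectivityNetwork | np.ndarray,
                  subset: np.ndarray | None = None) -> np.ndarray:
    """Sum of absolute edge weights from each retained node to the other
    retained nodes (absolute values make signed Pearson and RE networks
    comparable)."""
    W = net.W if isinstance(net, ConnectivityNetwork) else np.asarray(net)
    n = W.shape[0]
    if subset is None:
        subset = np.arange(n)
    subset = np.asarray(subset)
    if subset.size < 2:
        raise ValueError("node strength needs >= 2 retained nodes")
    sub = np.abs(W[np.ix_(subset, subset)])
    np.fill_diagonal(sub, 0.0)
    return np.nansum(sub, axis=1)


def subsample_reliability(net: ConnectivityNetwork | np.ndarray, fraction: float,
                          n_iter: int = 1000, seed: int | None = None,
                          exhaustive: bool = False) -> ReliabilityPoint:
    """Reliability of node strength under random removal of ``fraction`` of
    the channels.

    Strengths are recorded for whichever channels an iteration retains; a
    channel's error variance uses only the iterations in which it is
    retained (channels retained in fewer than 2 iterations are excluded from
    the sigma_E average, with a log note).  ``exhaustive=True`` replaces the
    random draws by the full enumeration of removal subsets (feasible only
    for small networks; used for oracle checks).
    """
    W = net.W if isinstance(net, ConnectivityNetwork) else np.asarray(net)
    n = W.shape[0]
    if not 0.0 < fraction < 1.0:
        raise ValueError("removal fraction must be in (0, 1)")
    n_remove = int(np.floor(fraction * n))
    n_keep = n - n_remove
    if n_keep < 2:
        raise ValueError(f"removing {n_remove} of {n} channels leaves < 2")

    if exhaustive:
        subsets = [np.array(keep)
                   for keep in itertools.combinations(range(n), n_keep)]
    else:
        rng = np.random.default_rng(seed)
        subsets = [np.sort(rng.choice(n, size=n_keep, replace=False))
                   for _ in range(n_iter)]

    strengths = np.full((len(subsets), n), np.nan)
    for it, keep in enumerate(subsets):
        strengths[it, keep] = node_strength(W, keep)

    # sigma_T: variance across retained contacts, averaged over iterations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_iter_var = np.nanvar(strengths, axis=1, ddof=1)
        sigma_T = float(np.nanmean(per_iter_var))
        # sigma_E: variance across iterations, averaged over contacts
        retained_counts = np.sum(np.isfinite(strengths), axis=0)
        ok = retained_counts >= 2
        if not ok.all():
            logger.info("subsample_reliability: %d contact(s) retained in < 2 "
                        "iterations excluded from sigma_E", int((~ok).sum()))
        # exhaustive mode holds the full subset population (ddof=0 is the
        # exact variance); sampling estimates that quantity unbiasedly
        per_contact_var = np.nanvar(strengths[:, ok], axis=0,
                                    ddof=0 if exhaustive else 1)
        sigma_E = float(np.nanmean(per_contact_var))

    if sigma_T == 0 and sigma_E == 0:
        warnings.warn("sigma_T and sigma_E are both zero; R undefined",
                      UserWarning, stacklevel=2)
        R = np.nan
    else:
        R = sigma_T / (sigma_T + sigma_E)
    return ReliabilityPoint(fraction=fraction, R=R, sigma_T=sigma_T,
                            sigma_E=sigma_E, n_iter=len(subsets))


def reliability_curve(net: ConnectivityNetwork, fractions=FRACTIONS,
                      n_iter: int = 1000, seed: int | None = None) -> ReliabilityCurve:
    curve = ReliabilityCurve(pipeline=getattr(net, "spec", None))
    for i, f in enumerate(fractions):
        curve.points.append(subsample_reliability(
            net, f, n_iter=n_iter, seed=None if seed is None else seed + i))
    return curve


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

def dunn_sidak_posthoc(X: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Rank-based pairwise comparisons after a Friedman test.

    Within-subject ranks are averaged per treatment; the difference of mean
    ranks is compared against SE = sqrt(k(k+1)/(6n)) with a two-sided normal
    test, Sidak-adjusted over the k(k-1)/2 pairs.
    """
    n, k = X.shape
    ranks = scipy.stats.rankdata(X, axis=1)
    mean_rank = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_rank[i] - mean_rank[j]) / se
            p = 2 * scipy.stats.norm.sf(abs(z))
            p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
            rows.append({"a": names[i], "b": names[j], "z": z, "p": p,
                         "p_sidak": p_adj, "significant": p_adj < 0.05})
    return pd.DataFrame(rows)


def compare_reliability(values: pd.DataFrame, grouping: str) -> dict:
    """Statistical comparison of reliability across pipeline groups.

    ``values``: patients x pipelines DataFrame of R, columns labelled
    "<scheme>-<measure>[-<band>]".  Grouping by "reference" runs a paired
    Wilcoxon signed-rank test on per-patient scheme means; "measure" and
    "band" average per group and run a Friedman test with Dunn-Sidak post
    hocs.  Patients with incomplete rows are dropped (logged).
    """
    complete = values.dropna(axis=0)
    if len(complete) < len(values):
        logger.info("compare_reliability: dropped %d incomplete patient row(s)",
                    len(values) - len(complete))
    if len(complete) < 5:
        raise ValueError("need >= 5 complete patients")

    def part(label, pos):
        bits = label.split("-")
        return bits[pos] if pos < len(bits) else None

    if grouping == "reference":
        groups = {}
        for scheme in ("car", "bipolar"):
            cols = [c for c in complete.columns if part(c, 0) == scheme]
            groups[scheme] = complete[cols].mean(axis=1)
        stat, p = scipy.stats.wilcoxon(groups["car"], groups["bipolar"],
                                       zero_method="zsplit")
        return {"grouping": "reference", "test": "wilcoxon_signed_rank",
                "statistic": float(stat), "p": float(p),
                "means": {k: float(v.mean()) for k, v in groups.items()}}

    pos = {"measure": 1, "band": 2}[grouping]
    levels = sorted({part(c, pos) for c in complete.columns
                     if part(c, pos) is not None})
    cols_per_level = {
        lev: [c for c in complete.columns if part(c, pos) == lev]
        for lev in levels}
    X = np.column_stack([complete[cols_per_level[lev]].mean(axis=1)
                         for lev in levels])
    stat, p = scipy.stats.friedmanchisquare(*(X[:, i] for i in range(X.shape[1])))
    posthoc = dunn_sidak_posthoc(X, levels)
    return {"grouping": grouping, "test": "friedman", "chi2": float(stat),
            "p": float(p), "levels": levels,
            "means": {lev: float(X[:, i].mean()) for i, lev in enumerate(levels)},
            "posthoc": posthoc}


def curves_to_frame(curves: dict, patient: str) -> pd.DataFrame:
    """Long-format export: patient, pipeline, fraction, R, sigma_T, sigma_E."""
    rows = []
    for spec, curve in curves.items():
        for pt in curve.points:
            rows.append({"patient": patient, "pipeline": spec.label,
                         "fraction": pt.fraction, "R": pt.R,
                         "sigma_T": pt.sigma_T, "sigma_E": pt.sigma_E})
    return pd.DataFrame(rows)
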