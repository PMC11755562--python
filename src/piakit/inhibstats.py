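"""Inhibition statistics for peptide-inhibitor-assay readouts.

The pipeline mirrors how the assay is scored: every replicate fluorescence
at the reference time is divided by the mean of the simultaneous
"no peptide" control (within its batch), each peptide is compared to the
control with Dunnett's many-to-one test, peptides are ranked by relative
intensity with a < 0.3 cut flagging the most inhibitory set, and descriptor
columns are correlated with relative intensity (Pearson).

The module-level functions implement the individual operations; the
:class:`InhibitionModel` / :class:`InhibitionResults` pair wraps them in a
fit/results interface with a ``summary()`` table.

Dunnett's adjusted p-values come from a seeded Monte Carlo sample of the
max-|t| statistic under the many-to-one null with a shared control: draw
group means z_i ~ N(0, 1/n_i), a pooled variance s^2 ~ chi2(df)/df, and
T_i = (z_i - z_0) / (s * sqrt(1/n_i + 1/n_0)); the adjusted p of an
observed t is the tail fraction of max_i |T_i| beyond |t|. The standard
independent-groups form is used throughout (a repeated-measures variant is
not attempted; the observed replicates are independent reactions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assaysim import CONTROL_ID

DEFAULT_MC_DRAWS = 100_000


# ---------------------------------------------------------------------------
# relative intensity

def relative_intensity(measurements: pd.DataFrame, ref_time: float = 3.0,
                       control_id: str = CONTROL_ID,
                       batch_col: str | None = None) -> pd.DataFrame:
    """Control-normalized fluorescence per peptide at the reference time.

    Each replicate is divided by the mean control fluorescence of its batch
    at ``ref_time`` (per-replicate-then-average convention). Returns a frame
    indexed by peptide id with columns rel_mean, rel_sd, n and no_band (all
    replicates zero: no measurable product band).
    """
    at_ref = measurements[measurements["time_h"] == ref_time]
    if at_ref.empty:
        raise ValueError(f"no measurements at reference time {ref_time}")
    batches = [(None, at_ref)] if batch_col is None else at_ref.groupby(batch_col)
    pieces = []
    for _, batch in batches:
        control = batch.loc[batch["peptide_id"] == control_id,
                            "fluorescence_au"]
        if control.empty:
            raise ValueError(f"control group {control_id!r} absent at "
                             f"t={ref_time}")
        control_mean = control.mean()
        if control_mean <= 0:
            raise ValueError("control mean fluorescence is not positive")
        norm = batch.assign(rel=batch["fluorescence_au"] / control_mean)
        pieces.append(norm)
    norm = pd.concat(pieces)
    grouped = norm.groupby("peptide_id")["rel"]
    out = pd.DataFrame({
        "rel_mean": grouped.mean(),
        "rel_sd": grouped.std(ddof=1),
        "n": grouped.size(),
    })
    out["no_band"] = grouped.apply(lambda s: bool((s == 0).all()))
    return out


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparison

def max_t_null_sample(group_sizes: Sequence[int], n_control: int,
                      n_draws: int = DEFAULT_MC_DRAWS,
                      seed: int = 0) -> np.ndarray:
    """Sorted Monte Carlo sample of max_i |T_i| under the many-to-one null."""
    sizes = np.asarray(group_sizes, dtype=int)
    if (sizes < 2).any() or n_control < 2:
        raise ValueError("need >= 2 observations per group")
    df = int(sizes.sum() + n_control - len(sizes) - 1)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(sizes))) / np.sqrt(sizes)
    z0 = rng.standard_normal((n_draws, 1)) / np.sqrt(n_control)
    s = np.sqrt(rng.chisquare(df, size=(n_draws, 1)) / df)
    t = (z - z0) / (s * np.sqrt(1.0 / sizes + 1.0 / n_control))
    return np.sort(np.abs(t).max(axis=1))


@dataclass(frozen=True)
class DunnettResult:
    statistics: np.ndarray
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    df: int


def dunnett_test(groups: Sequence[np.ndarray] | Mapping[str, np.ndarray],
                 control: np.ndarray,
                 n_draws: int = DEFAULT_MC_DRAWS, seed: int = 0,
                 null_sample: np.ndarray | None = None) -> DunnettResult:
    """Two-sided many-to-one comparisons of each group against a control.

    ``null_sample`` may supply a precomputed :func:`max_t_null_sample` for
    the same design (group count and sizes), which makes repeated calls
    cheap. Adjusted p-values are clipped from below by the raw two-sample p
    (the Monte Carlo tail estimate cannot legitimately fall under it) and
    are monotone in |t| by construction.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    control = np.asarray(control, dtype=float)
    if not arrays:
        raise ValueError("need at least one treatment group")
    sizes = np.array([len(g) for g in arrays])
    n0 = len(control)
    if (sizes < 2).any() or n0 < 2:
        raise ValueError("need >= 2 observations per group")
    df = int(sizes.sum() + n0 - len(arrays) - 1)
    pooled_ss = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    pooled_ss += ((control - control.mean()) ** 2).sum()
    if pooled_ss == 0:
        raise ValueError("degenerate data: zero variance in every group")
    s2 = pooled_ss / df
    means = np.array([g.mean() for g in arrays])
    t_obs = (means - control.mean()) / np.sqrt(s2 * (1.0 / sizes + 1.0 / n0))
    raw_p = 2.0 * stats.t.sf(np.abs(t_obs), df)
    if null_sample is None:
        null_sample = max_t_null_sample(sizes, n0, n_draws=n_draws, seed=seed)
    tail = len(null_sample) - np.searchsorted(null_sample, np.abs(t_obs),
                                              side="left")
    adjusted = tail / len(null_sample)
    adjusted = np.clip(adjusted, raw_p, 1.0)
    return DunnettResult(t_obs, raw_p, adjusted, df)


def t_test_summary(n1: int, mean1: float, sd1: float,
                   n2: int, mean2: float, sd2: float) -> float:
    """Two-sided pooled-variance Student's t-test p from summary statistics."""
    result = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                        equal_var=True)
    return float(result.pvalue)


def significance_stars(p: float, alpha: float = 0.05,
                       alpha_strong: float = 0.01) -> str:
    if p < alpha_strong:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# ranking and correlation

def rank_and_classify(results: pd.DataFrame,
                      threshold: float = 0.3) -> pd.DataFrame:
    """Rank peptides by relative intensity (1 = most inhibitory).

    Adds ``rank`` and ``most_inhibitory`` (rel_mean strictly below the
    threshold). Ties in rel_mean break by peptide id, lexicographically.
    """
    out = results.copy()
    order = out.reset_index().sort_values(
        ["rel_mean", out.index.name or "peptide_id"]).set_index(
        out.index.name or "peptide_id")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = ranks
    out["most_inhibitory"] = out["rel_mean"] < threshold
    return out.sort_values("rank")


@dataclass(frozen=True)
class CorrelationResult:
    descriptor_name: str
    pearson_r: float
    p_value: float
    n: int
    error: str | None = None


def correlate_descriptors(results: pd.DataFrame,
                          descriptor_table: pd.DataFrame,
                          factors: Iterable[str] | None = None,
                          exclude: Iterable[str] = ()) -> list[CorrelationResult]:
    """Pearson correlation of each descriptor with relative intensity.

    Peptides on ``exclude`` are dropped before pairing (the published
    analysis excludes the nuclease-inducing peptide and its deletion
    fragments). A constant factor yields a CorrelationResult with an error
    note instead of raising.
    """
    merged = results.join(descriptor_table, how="inner")
    merged = merged.drop(index=[p for p in exclude if p in merged.index])
    if len(merged) < 3:
        raise ValueError("need at least 3 paired observations")
    if factors is None:
        factors = [c for c in descriptor_table.columns
                   if pd.api.types.is_numeric_dtype(descriptor_table[c])]
    out = []
    for factor in factors:
        x = merged[factor].astype(float)
        y = merged["rel_mean"].astype(float)
        if x.nunique() <= 1:
            out.append(CorrelationResult(factor, float("nan"), float("nan"),
                                         len(merged), "constant factor"))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(factor, float(r), float(p), len(merged)))
    return out


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("descriptor_name")


# ---------------------------------------------------------------------------
# model / results interface

class InhibitionModel:
    """Many-to-one inhibition analysis of a measurement table.

    Parameters
    ----------
    measurements : tidy frame with columns peptide_id, dose, time_h,
        replicate, fluorescence_au (the simulator's output format).
    ref_time : scoring time in hours.
    control_id : identifier of the no-peptide control group.
    batch_col : optional column naming the assay batch; normalization and
        testing are then within-batch against each batch's own control.
    """

    def __init__(self, measurements: pd.DataFrame, ref_time: float = 3.0,
                 control_id: str = CONTROL_ID,
                 batch_col: str | None = None) -> None:
        required = {"peptide_id", "time_h", "fluorescence_au"}
        missing = required - set(measurements.columns)
        if missing:
            raise ValueError(f"measurements lack columns {sorted(missing)}")
        self.measurements = measurements
        self.ref_time = ref_time
        self.control_id = control_id
        self.batch_col = batch_col

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "InhibitionModel":
        from .assaysim import read_measurements
        return cls(read_measurements(path), **kwargs)

    def fit(self, threshold: float = 0.3, alpha: float = 0.05,
            n_draws: int = DEFAULT_MC_DRAWS, seed: int = 0) -> "InhibitionResults":
        rel = relative_intensity(self.measurements, self.ref_time,
                                 self.control_id, self.batch_col)
        at_ref = self.measurements[self.measurements["time_h"] == self.ref_time]
        peptide_ids = [p for p in rel.index if p != self.control_id]
        groups = [at_ref.loc[at_ref["peptide_id"] == p,
                             "fluorescence_au"].to_numpy()
                  for p in peptide_ids]
        control = at_ref.loc[at_ref["peptide_id"] == self.control_id,
                             "fluorescence_au"].to_numpy()
        dunnett = dunnett_test(groups, control, n_draws=n_draws, seed=seed)
        table = rel.loc[peptide_ids].copy()
        table["raw_p"] = dunnett.raw_p
        table["adj_p"] = dunnett.adjusted_p
        table["stars"] = [significance_stars(p, alpha) for p in
                          dunnett.adjusted_p]
        table = rank_and_classify(table, threshold)
        return InhibitionResults(self, table, threshold, alpha, seed)


class InhibitionResults:
    """Fitted inhibition analysis: per-peptide estimates, Dunnett-adjusted
    p-values, significance stars and ranks."""

    def __init__(self, model: InhibitionModel, table: pd.DataFrame,
                 threshold: float, alpha: float, seed: int) -> None:
        self.model = model
        self.frame = table
        self.threshold = threshold
        self.alpha = alpha
        self.seed = seed

    @property
    def most_inhibitory(self) -> list[str]:
        """Peptides with relative intensity strictly below the threshold,
        most inhibitory first."""
        sub = self.frame[self.frame["most_inhibitory"]]
        return list(sub.index)

    def correlate(self, descriptor_table: pd.DataFrame,
                  factors: Iterable[str] | None = None,
                  exclude: Iterable[str] = ()) -> pd.DataFrame:
        results = correlate_descriptors(self.frame, descriptor_table,
                                        factors, exclude)
        return correlation_frame(results)

    def summary(self) -> str:
        lines = [
            "Peptide inhibitor assay: many-to-one inhibition analysis",
            f"  reference time: {self.model.ref_time} h   "
            f"control: {self.model.control_id}",
            f"  peptides: {len(self.frame)}   threshold: "
            f"rel. intensity < {self.threshold}   alpha: {self.alpha}",
            "",
            self.frame[["rel_mean", "rel_sd", "n", "raw_p", "adj_p",
                        "stars", "rank"]].to_string(
                float_format=lambda v: f"{v:.4g}"),
            "",
            f"most inhibitory (< {self.threshold}): "
            + (", ".join(self.most_inhibitory) or "none"),
        ]
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")
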