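"""The fatigue-study analysis chain.

A sustained-contraction recording is split into four equal consecutive
windows W1..W4 (chronological quarters of time-to-exhaustion).  Each
window is reduced to an entropy-vs-scale profile for one or more
estimators; pairwise window differences of those profiles localize the
scale that best separates fatigue stages; a repeated-measures ANOVA with
Bonferroni post-hoc tests quantifies the separation across subjects.

The scale grid defaults to 1..100, dimension to 3..5, and for the
downsampling estimators the decimation factor is tied to the scale
(tau = m) so all methods are compared at the same effective rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.diagnostic import lilliefors

from .downsampling import cdpe, dpe, rcdpe
from .multiscale import cmpe, mpe, rcmpe
from .ordinal import permutation_entropy
from .synthetic import CohortSpec, FatigueSubject, gen_fatigue_cohort
from .types import EntropyValue, PESettings, Signal

__all__ = [
    "DEFAULT_PAIRS",
    "EntropyProfile",
    "DeltaTable",
    "FatigueStudyResult",
    "segment_windows",
    "entropy_value",
    "entropy_profile",
    "cohort_profiles",
    "pairwise_deltas",
    "select_scale",
    "run_statistics",
    "run_fatigue_study",
]

#: The five window contrasts entered in the delta analysis.
DEFAULT_PAIRS = (("W1", "W2"), ("W1", "W3"), ("W1", "W4"), ("W2", "W3"), ("W3", "W4"))


def segment_windows(signal: Signal, n_windows: int = 4) -> list[Signal]:
    """Split a signal into ``n_windows`` equal consecutive windows.

    Each window holds ``floor(N / n_windows)`` samples; any remainder is
    dropped from the end of the record.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if len(signal) < n_windows:
        raise ValueError(f"signal of {len(signal)} samples cannot fill {n_windows} windows")
    w = len(signal) // n_windows
    return [
        Signal(signal.samples[i * w : (i + 1) * w], signal.fs, label=f"{signal.label}/W{i + 1}")
        for i in range(n_windows)
    ]


def entropy_value(
    signal: Signal | np.ndarray,
    method: str,
    scale: int,
    d: int = 3,
    normalized: bool = True,
    tie_policy: str = "earlier",
    tie_seed: int = 0,
) -> EntropyValue:
    """Dispatch one entropy computation by estimator name.

    ``scale`` is the coarse-graining scale m for the multiscale family and
    the decimation factor tau for the downsampling family; for plain PE it
    is the embedding delay tau.
    """
    kw = dict(d=d, normalized=normalized, tie_policy=tie_policy, tie_seed=tie_seed)
    if method == "PE":
        s = PESettings(d=d, tau=scale, normalized=normalized, tie_policy=tie_policy, tie_seed=tie_seed)
        return permutation_entropy(signal, s)
    if method == "MPE":
        return mpe(signal, scale, **kw)
    if method == "cMPE":
        return cmpe(signal, scale, **kw)
    if method == "rcMPE":
        return rcmpe(signal, scale, **kw)
    if method == "DPE":
        return dpe(signal, scale, **kw)
    if method == "cDPE":
        return cdpe(signal, scale, **kw)
    if method == "rcDPE":
        return rcdpe(signal, scale, **kw)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EntropyProfile:
    """Entropy per scale for one (signal, method, dimension) combination."""

    method: str
    d: int
    scales: np.ndarray
    values: np.ndarray
    subject: str = ""
    window: str = ""

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if self.scales.shape != self.values.shape:
            raise ValueError("scales and values must align")


def entropy_profile(
    signal: Signal,
    method: str,
    d: int = 3,
    scales: Sequence[int] = range(1, 101),
    normalized: bool = True,
    tie_policy: str = "earlier",
) -> EntropyProfile:
    """Entropy of one signal at every scale of the grid."""
    scales = np.asarray(list(scales), dtype=np.int64)
    values = [
        entropy_value(signal, method, int(m), d=d, normalized=normalized, tie_policy=tie_policy).value
        for m in scales
    ]
    return EntropyProfile(method=method, d=d, scales=scales, values=np.array(values), subject=signal.label)


def cohort_profiles(
    cohort: Iterable[FatigueSubject],
    methods: Sequence[str] = ("MPE", "rcMPE", "rcDPE"),
    dims: Sequence[int] = (3, 4, 5),
    scales: Sequence[int] = range(1, 101),
    normalized: bool = True,
    tie_policy: str = "earlier",
) -> pd.DataFrame:
    """Tidy per-window entropy profiles for a whole cohort.

    Returns a long-format frame with columns
    ``subject, window, method, d, scale, value``.
    """
    scales = list(scales)
    rows = []
    for subj in cohort:
        for i, win in enumerate(subj.windows):
            wname = f"W{i + 1}"
            for method in methods:
                for d in dims:
                    prof = entropy_profile(
                        win, method, d=d, scales=scales, normalized=normalized, tie_policy=tie_policy
                    )
                    for m, v in zip(prof.scales, prof.values):
                        rows.append((subj.subject_id, wname, method, d, int(m), float(v)))
    return pd.DataFrame(rows, columns=["subject", "window", "method", "d", "scale", "value"])


@dataclass
class DeltaTable:
    """Pairwise window entropy differences in long format."""

    pairs: tuple[tuple[str, str], ...]
    table: pd.DataFrame  # columns: subject, pair, method, d, scale, delta


def pairwise_deltas(
    profiles: pd.DataFrame, pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS
) -> DeltaTable:
    """Earlier-window minus later-window entropy for each configured pair."""
    keys = ["subject", "method", "d", "scale"]
    wide = profiles.pivot_table(index=keys, columns="window", values="value")
    frames = []
    for early, late in pairs:
        if early not in wide.columns or late not in wide.columns:
            raise ValueError(f"window pair ({early}, {late}) missing from profiles")
        f = (wide[early] - wide[late]).rename("delta").reset_index()
        f.insert(1, "pair", f"{early}-{late}")
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    return DeltaTable(pairs=tuple((a, b) for a, b in pairs), table=table)


def select_scale(
    deltas: DeltaTable | pd.DataFrame,
    method: str | None = None,
    d: int | None = None,
) -> int:
    """Scale maximizing the mean absolute delta across subjects and pairs.

    Ties break toward the smallest scale.  ``method``/``d`` restrict the
    selection to one estimator configuration.
    """
    tab = deltas.table if isinstance(deltas, DeltaTable) else deltas
    if method is not None:
        tab = tab[tab["method"] == method]
    if d is not None:
        tab = tab[tab["d"] == d]
    if tab.empty:
        raise ValueError("no delta rows match the requested method/dimension")
    crit = tab.assign(absdelta=tab["delta"].abs()).groupby("scale")["absdelta"].mean()
    crit = crit.sort_index()  # ties -> idxmax returns the first (smallest) scale
    return int(crit.idxmax())


def _bonferroni_pairs(wide: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests between all level pairs, Bonferroni-adjusted."""
    levels = list(wide.columns)
    n_tests = len(levels) * (len(levels) - 1) // 2
    rows = []
    for a, b in combinations(levels, 2):
        t, p = spstats.ttest_rel(wide[a], wide[b])
        rows.append((a, b, float(t), min(1.0, float(p) * n_tests)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "t", "p_bonferroni"])


def run_statistics(
    table: pd.DataFrame,
    depvar: str,
    within: Sequence[str],
    subject: str = "subject",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Repeated-measures ANOVA over within-subject factors, with post-hocs.

    ``table`` must be a balanced long-format frame: every subject
    contributes exactly one observation per factor-level combination.
    Returns the ANOVA table, Bonferroni-adjusted pairwise post-hoc tests
    per factor (averaging over the other factors), and normality /
    equal-variance screening (Lilliefors on the per-cell residuals,
    Levene across the first factor's levels) — screening is reported,
    never used to gate the analysis.
    """
    within = list(within)
    counts = table.groupby([subject, *within], observed=True).size()
    if (counts != 1).any():
        raise ValueError(
            "unbalanced design: every subject needs exactly one observation "
            "per combination of " + " x ".join(within)
        )
    aov = AnovaRM(table, depvar=depvar, subject=subject, within=within).fit()
    anova_table = aov.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    anova_table["significant"] = anova_table["p"] < alpha

    posthoc = {}
    for factor in within:
        wide = table.pivot_table(index=subject, columns=factor, values=depvar, observed=True)
        posthoc[factor] = _bonferroni_pairs(wide)

    cell_means = table.groupby(within, observed=True)[depvar].transform("mean")
    resid = (table[depvar] - cell_means).to_numpy()
    lf_stat, lf_p = lilliefors(resid, dist="norm")
    groups = [g[depvar].to_numpy() for _, g in table.groupby(within[0], observed=True)]
    lev_stat, lev_p = spstats.levene(*groups)
    screening = pd.DataFrame(
        {
            "test": ["lilliefors_residual_normality", f"levene_{within[0]}"],
            "statistic": [float(lf_stat), float(lev_stat)],
            "p": [float(lf_p), float(lev_p)],
        }
    )

    out = {"anova": anova_table, "screening": screening}
    for factor, frame in posthoc.items():
        out[f"posthoc_{factor}"] = frame
    return out


@dataclass
class FatigueStudyResult:
    """Everything the windowed fatigue analysis produces."""

    profiles: pd.DataFrame
    deltas: DeltaTable
    selected_scale: int
    anova_deltas: dict[str, pd.DataFrame]
    anova_windows: dict[str, pd.DataFrame]
    spec: CohortSpec | None = None
    selection_method: str = "rcDPE"
    selection_d: int = 4

    def window_means(self, method: str = "rcDPE", d: int = 4, scale: int | None = None) -> pd.Series:
        """Mean entropy per window at one (method, d, scale) setting."""
        scale = self.selected_scale if scale is None else scale
        p = self.profiles
        sel = p[(p["method"] == method) & (p["d"] == d) & (p["scale"] == scale)]
        return sel.groupby("window")["value"].mean()


def run_fatigue_study(
    cohort: Iterable[FatigueSubject] | CohortSpec | None = None,
    methods: Sequence[str] = ("MPE", "rcMPE", "rcDPE"),
    dims: Sequence[int] = (3, 4, 5),
    scales: Sequence[int] = range(1, 101),
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    selection_method: str = "rcDPE",
    selection_d: int = 4,
    normalized: bool = True,
    tie_policy: str = "earlier",
    alpha: float = 0.05,
) -> FatigueStudyResult:
    """Full chain: windows -> profiles -> deltas -> scale -> statistics.

    ``cohort`` may be a list of :class:`FatigueSubject` or a
    :class:`CohortSpec` (simulated on the fly; ``None`` uses the default
    spec).  Two ANOVAs are run: one on the pairwise deltas at the selected
    scale (within factors: pair, method and — when several are scanned —
    dimension) and a one-way on the raw window entropies of the selection
    estimator at the selected scale (the fatigue factor proper).
    """
    spec = None
    if cohort is None:
        spec = CohortSpec()
        cohort = gen_fatigue_cohort(spec)
    elif isinstance(cohort, CohortSpec):
        spec = cohort
        cohort = gen_fatigue_cohort(spec)
    else:
        cohort = list(cohort)

    profiles = cohort_profiles(
        cohort, methods=methods, dims=dims, scales=scales, normalized=normalized, tie_policy=tie_policy
    )
    deltas = pairwise_deltas(profiles, pairs=pairs)
    sel = select_scale(deltas, method=selection_method, d=selection_d)

    at_scale = deltas.table[deltas.table["scale"] == sel].copy()
    within = ["pair"]
    if len(methods) > 1:
        within.append("method")
    if len(dims) > 1:
        within.append("d")
    anova_deltas = run_statistics(at_scale, depvar="delta", within=within, alpha=alpha)

    p = profiles
    win_tab = p[
        (p["method"] == selection_method) & (p["d"] == selection_d) & (p["scale"] == sel)
    ].copy()
    anova_windows = run_statistics(win_tab, depvar="value", within=["window"], alpha=alpha)

    return FatigueStudyResult(
        profiles=profiles,
        deltas=deltas,
        selected_scale=sel,
        anova_deltas=anova_deltas,
        anova_windows=anova_windows,
        spec=spec,
        selection_method=selection_method,
        selection_d=selection_d,
    )
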