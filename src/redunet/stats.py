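"""Treatment-contrast statistics.

Per-functional-category one-way ANOVA across the four grazing x phosphorus
treatments with Tukey's honestly-significant-difference post hoc and compact
letter display, plus the dominant-species reciprocal-shift analysis: how much
relative abundance the sensitive dominant loses per treatment, how much the
complementary dominant gains, and whether the two shifts cancel
(complementarity c = 1 means exact cancellation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryTestResult",
    "ReciprocalShiftReport",
    "tukey_pairwise",
    "compact_letter_display",
    "anova_tukey",
    "reciprocal_shift",
]


@dataclass
class CategoryTestResult:
    category: str
    func_class: str | None
    F: float
    p: float
    tukey: pd.DataFrame          # group x group adjusted p-values
    letters: dict[str, str]      # treatment -> compact letters
    alpha: float = 0.05


def tukey_pairwise(groups: list[np.ndarray]) -> np.ndarray:
    """Tukey HSD adjusted p-value matrix for a list of group samples."""
    res = sps.tukey_hsd(*groups)
    return res.pvalue


def compact_letter_display(
    pairwise_p: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; each significant
    pair must share no letter.  Letters are assigned in group order so output
    is deterministic.
    """
    groups = list(pairwise_p.index)
    columns: list[set] = [set(groups)]
    for g1, g2 in combinations(groups, 2):
        if pairwise_p.loc[g1, g2] >= alpha:
            continue
        new_cols = []
        for col in columns:
            if g1 in col and g2 in col:
                new_cols.append(col - {g1})
                new_cols.append(col - {g2})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = [c for c in new_cols
                   if not any(c < other for other in new_cols) and c]
        # dedupe while keeping order
        seen, uniq = [], []
        for c in columns:
            if c not in seen:
                seen.append(c)
                uniq.append(c)
        columns = uniq
    # order columns by their first group, assign letters a, b, c, ...
    columns.sort(key=lambda c: min(groups.index(g) for g in c))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in col:
            letters[g] += ch
    letters = {g: "".join(sorted(v)) for g, v in letters.items()}
    _check_letters(pairwise_p, letters, alpha)
    return letters


def _check_letters(pairwise_p: pd.DataFrame, letters: dict[str, str], alpha: float) -> None:
    # invariant: shared letter <=> not significantly different
    for g1, g2 in combinations(pairwise_p.index, 2):
        share = bool(set(letters[g1]) & set(letters[g2]))
        sig = pairwise_p.loc[g1, g2] < alpha
        if share == sig:
            raise AssertionError(
                f"compact letters inconsistent with Tukey p for ({g1}, {g2}): "
                f"p={pairwise_p.loc[g1, g2]:.4g}, letters {letters[g1]}/{letters[g2]}"
            )


def anova_tukey(
    category_table: AbundanceTable,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    post_hoc: bool = True,
) -> list[CategoryTestResult]:
    """One-way fixed-effects ANOVA across treatments per category, with Tukey
    HSD pairwise tests and compact letters.

    Categories where some treatment has fewer than 2 replicates are skipped
    with a warning.  A category with zero variance everywhere is reported with
    the degenerate convention F = 0, p = 1, all treatments lettered "a".
    ``post_hoc=False`` skips the (comparatively slow) Tukey step and reports
    only F and p — useful in simulation loops that read only the ANOVA.
    """
    meta = metadata.loc[category_table.samples]
    treatments = sorted(meta["treatment"].unique())
    results: list[CategoryTestResult] = []
    for cat in category_table.features:
        vals = category_table.data[cat]
        groups = [vals[meta["treatment"] == t].values for t in treatments]
        if any(len(g) < 2 for g in groups):
            logger.warning("anova_tukey: skipping %r (a treatment has < 2 replicates)", cat)
            continue
        allv = np.concatenate(groups)
        if np.allclose(allv, allv[0]):
            pmat = pd.DataFrame(1.0, index=treatments, columns=treatments)
            results.append(CategoryTestResult(cat, None, 0.0, 1.0, pmat,
                                              {t: "a" for t in treatments}, alpha))
            continue
        F, p = sps.f_oneway(*groups)
        if post_hoc:
            pmat = pd.DataFrame(tukey_pairwise(groups), index=treatments, columns=treatments)
            letters = compact_letter_display(pmat, alpha)
        else:
            pmat, letters = None, {}
        results.append(CategoryTestResult(cat, None, float(F), float(p), pmat, letters, alpha))
    return results


@dataclass
class ReciprocalShiftReport:
    """Per-treatment shifts of species relative abundance vs the control."""

    delta: pd.DataFrame               # treatments (non-control) x species
    decreasing_species: dict[str, str]
    increasing_species: dict[str, str]
    complementarity: dict[str, float]
    dominance: float                  # combined mean share of the top-2 species
    control: str

    @property
    def max_shift_treatment(self) -> str:
        """Treatment with the largest |shift| of the extreme species pair."""
        mags = {
            t: abs(self.delta.loc[t, self.decreasing_species[t]])
            + abs(self.delta.loc[t, self.increasing_species[t]])
            for t in self.delta.index
        }
        return max(mags, key=mags.get)


def reciprocal_shift(
    species_table: AbundanceTable,
    metadata: pd.DataFrame,
    control: str = "G-P-",
) -> ReciprocalShiftReport:
    """Shifts of mean species share per treatment relative to the control.

    delta_s(t) = mean share of s under t - mean share under control.  The
    decreasing/increasing species are the argmin/argmax of delta per treatment
    and complementarity c = 1 - |d_dec + d_inc| / (|d_dec| + |d_inc|) is 1 for
    exact cancellation and 0 for same-signed shifts.
    """
    meta = metadata.loc[species_table.samples]
    if control not in set(meta["treatment"]):
        raise ValueError(f"control treatment {control!r} not present in metadata")
    rel = species_table.data.div(species_table.data.sum(axis=1), axis=0)
    mean_share = rel.groupby(meta["treatment"]).mean()
    delta = mean_share.drop(index=control) - mean_share.loc[control]

    decreasing, increasing, comp = {}, {}, {}
    for t in delta.index:
        row = delta.loc[t]
        dec, inc = row.idxmin(), row.idxmax()
        d, i = row[dec], row[inc]
        denom = abs(d) + abs(i)
        comp[t] = float(1.0 - abs(d + i) / denom) if denom > 0 else 0.0
        decreasing[t], increasing[t] = dec, inc
    top2 = mean_share.mean(axis=0).nlargest(2)
    return ReciprocalShiftReport(
        delta=delta,
        decreasing_species=decreasing,
        increasing_species=increasing,
        complementarity=comp,
        dominance=float(top2.sum()),
        control=control,
    )
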