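"""Threshold-bin phenotype comparisons for the TNSV burden.

Accessions are partitioned into low / mid / high burden bins (TNSV < 10,
10 <= TNSV <= 20, TNSV > 20 by default) and phenotype differences between
bins are tested with a one-way ANOVA, all pairwise two-sided Welch t-tests,
and a Tukey HSD compact-letter display. The scan runs per gene family and
on the aggregate burden, for both traits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .tnsv_scoring import TNSVTable

__all__ = [
    "BinSpec",
    "AssociationResult",
    "bin_by_tnsv",
    "compare_bins",
    "per_family_scan",
]


@dataclass(frozen=True)
class BinSpec:
    """Three burden bins split at two thresholds.

    Edge assignment: a value equal to either threshold lands in the middle
    bin, i.e. low: t < lo, mid: lo <= t <= hi, high: t > hi.
    """

    thresholds: tuple[float, float] = (10.0, 20.0)
    labels: tuple[str, str, str] = ("low", "mid", "high")

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be strictly increasing")

    def assign(self, value: float) -> str:
        lo, hi = self.thresholds
        if value < lo:
            return self.labels[0]
        if value > hi:
            return self.labels[2]
        return self.labels[1]


@dataclass
class AssociationResult:
    """Bin statistics and tests for one trait under one burden scope."""

    trait: str
    scope: str
    bin_stats: pd.DataFrame  # index bin label; columns n, mean, sd
    anova_f: Optional[float]
    anova_p: Optional[float]
    pairwise: pd.DataFrame  # bin_a, bin_b, t, p
    letters: dict[str, str] = field(default_factory=dict)
    testable: bool = True
    reason: str = ""

    def report(self) -> str:
        lines = [f"trait={self.trait} scope={self.scope}"]
        if not self.testable:
            lines.append(f"  not testable: {self.reason}")
        for label, row in self.bin_stats.iterrows():
            letter = self.letters.get(label, "")
            lines.append(
                f"  {label:>5}: n={int(row['n']):4d} mean={row['mean']:.3f} "
                f"sd={row['sd']:.3f} {letter}"
            )
        if self.testable:
            lines.append(f"  ANOVA F={self.anova_f:.3f} p={self.anova_p:.3g}")
            for _, r in self.pairwise.iterrows():
                lines.append(
                    f"  {r['bin_a']} vs {r['bin_b']}: t={r['t']:.3f} p={r['p']:.3g}"
                )
        return "\n".join(lines)


def bin_by_tnsv(
    tnsv_table: TNSVTable, spec: BinSpec = BinSpec(), scope: str = "aggregate"
) -> pd.Series:
    """Bin label per accession under the given scope.

    ``scope`` is ``"aggregate"``, ``"family:<name>"`` or ``"gene:<id>"``;
    an unknown scope raises KeyError. Every accession lands in exactly one
    bin; empty bins are legitimate.
    """
    values = tnsv_table.scope(scope)
    labels = values.map(spec.assign)
    labels.name = "bin"
    return labels


def _tukey_letters(
    values: pd.Series, bins: pd.Series, usable: list[str], alpha: float
) -> dict[str, str]:
    """Compact letter display from Tukey HSD: bins sharing a letter are not
    significantly different. Maximal mutually-nonsignificant sets get one
    letter each (exhaustive over subsets; bin counts are tiny)."""
    if len(usable) < 2:
        return {usable[0]: "a"} if usable else {}
    res = pairwise_tukeyhsd(values.to_numpy(), bins.to_numpy(), alpha=alpha)
    groups = list(res.groupsunique)
    different = set()
    summary = np.asarray(res._results_table.data[1:], dtype=object)
    for row in summary:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[6])
        if reject:
            different.add(frozenset((g1, g2)))

    def compatible(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) not in different
            for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for r in range(len(groups), 0, -1):
        for subset in itertools.combinations(groups, r):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    means = values.groupby(bins).mean()
    cliques.sort(key=lambda c: -means[list(c)].mean())
    letters: dict[str, str] = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return {str(g): v for g, v in letters.items()}


def compare_bins(
    bins: pd.Series,
    phenotypes: pd.DataFrame,
    trait: str,
    scope: str = "aggregate",
    alpha: float = 0.05,
    letters: bool = True,
    label_order: Sequence[str] = ("low", "mid", "high"),
) -> AssociationResult:
    """Test phenotype differences between burden bins.

    Accessions missing the trait are dropped for that trait only. Bins with
    fewer than 2 observations are reported but excluded from testing; with
    fewer than 2 usable bins the result is explicitly "not testable".
    """
    y = phenotypes[trait]
    joined = pd.DataFrame({"bin": bins, "y": y}).dropna()
    present = set(bins.dropna().unique())
    all_labels = list(label_order) + sorted(present - set(label_order))
    grp = joined.groupby("bin")["y"]
    stats_rows = []
    for label in all_labels:
        if label in grp.groups:
            vals = grp.get_group(label)
            stats_rows.append(
                {"bin": label, "n": len(vals), "mean": vals.mean(),
                 "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan}
            )
        else:
            stats_rows.append({"bin": label, "n": 0, "mean": np.nan, "sd": np.nan})
    bin_stats = pd.DataFrame(stats_rows).set_index("bin")

    usable = [l for l in all_labels if l in grp.groups and len(grp.get_group(l)) >= 2]
    if len(usable) < 2:
        return AssociationResult(
            trait=trait, scope=scope, bin_stats=bin_stats,
            anova_f=None, anova_p=None,
            pairwise=pd.DataFrame(columns=["bin_a", "bin_b", "t", "p"]),
            testable=False,
            reason=f"fewer than 2 bins with n >= 2 (usable: {usable})",
        )

    samples = [grp.get_group(l).to_numpy() for l in usable]
    f_stat, f_p = stats.f_oneway(*samples)
    pairs = []
    for (la, a), (lb, b) in itertools.combinations(zip(usable, samples), 2):
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pairs.append({"bin_a": la, "bin_b": lb, "t": float(t), "p": float(p)})
    pairwise = pd.DataFrame(pairs, columns=["bin_a", "bin_b", "t", "p"])

    letter_map: dict[str, str] = {}
    if letters:
        mask = joined["bin"].isin(usable)
        letter_map = _tukey_letters(
            joined.loc[mask, "y"], joined.loc[mask, "bin"], usable, alpha
        )
    return AssociationResult(
        trait=trait, scope=scope, bin_stats=bin_stats,
        anova_f=float(f_stat), anova_p=float(f_p),
        pairwise=pairwise, letters=letter_map,
    )


def per_family_scan(
    tnsv_table: TNSVTable,
    phenotypes: pd.DataFrame,
    spec: BinSpec = BinSpec(),
    traits: Sequence[str] = ("soc", "oac"),
    families: Optional[Sequence[str]] = None,
    letters: bool = True,
) -> list[AssociationResult]:
    """One AssociationResult per gene family per trait.

    A family in which every accession has zero burden puts everyone in the
    low bin and comes back "not testable" rather than silently passing.
    """
    fams = list(families) if families is not None else list(tnsv_table.per_family.columns)
    results = []
    for fam in fams:
        scope = f"family:{fam}"
        bins = bin_by_tnsv(tnsv_table, spec, scope)
        for trait in traits:
            results.append(
                compare_bins(bins, phenotypes, trait, scope=scope, letters=letters)
            )
    return results
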