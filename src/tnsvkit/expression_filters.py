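"""Expression-based candidate gating.

Applies the published thresholds to per-gene expression statistics: an
expressed/not-expressed call (FPKM > 1 at either stage), Benjamini-Hochberg
FDR adjustment of differential-expression p-values with an up/down/unchanged
call (FDR < 0.05 and |log2FC| >= 1), qPCR delta-Ct relative expression
(2^-dCt), and a three-criterion candidate ranking: (i) significant burden
association, (ii) differential expression between early and late seed
development, (iii) expression peaking in the 35-55 DAP window.

The negative-binomial model that produces the fold changes and p-values is
deliberately not part of this module; only the thresholds are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "classify_expressed",
    "bh_adjust",
    "de_classify",
    "relative_expression",
    "select_candidates",
]


def classify_expressed(
    fpkm: pd.DataFrame, threshold: float = 1.0
) -> pd.Series:
    """Expressed iff FPKM strictly exceeds ``threshold`` at any stage.

    ``fpkm`` is genes x stages. A gene at exactly the threshold in every
    stage is *not* expressed. Negative abundances are a data error.
    """
    values = fpkm.to_numpy(dtype=float)
    if np.any(values < 0):
        bad = fpkm.index[np.any(values < 0, axis=1)][0]
        raise ValueError(f"negative FPKM for gene {bad!r}")
    flags = (fpkm > threshold).any(axis=1)
    flags.name = "expressed"
    return flags


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_classify(
    de_inputs: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> pd.Series:
    """Per-gene call in {up, down, unchanged} at the published thresholds.

    ``de_inputs`` has columns ``log2fc`` and ``pvalue`` indexed by gene; BH
    adjustment is applied internally. up: FDR < 0.05 and log2FC >= 1 (late
    relative to early stage); down: FDR < 0.05 and log2FC <= -1; everything
    else, including genes below the fold-change cut, is unchanged.
    """
    adj = bh_adjust(de_inputs["pvalue"].to_numpy())
    log2fc = de_inputs["log2fc"].to_numpy(dtype=float)
    call = np.where(
        (adj < fdr) & (log2fc >= lfc),
        "up",
        np.where((adj < fdr) & (log2fc <= -lfc), "down", "unchanged"),
    )
    return pd.Series(call, index=de_inputs.index, name="de_class")


def relative_expression(ct_target: float, ct_control: float) -> tuple[float, float]:
    """qPCR relative expression: dCt = Ct_target - Ct_control, level 2^-dCt."""
    if ct_target <= 0 or ct_control <= 0:
        raise ValueError("Ct values must be positive")
    dct = ct_target - ct_control
    return dct, 2.0 ** (-dct)


@dataclass(frozen=True)
class _CriterionFlags:
    association: Optional[bool]
    differential: Optional[bool]
    peak_window: Optional[bool]

    @property
    def rank(self) -> int:
        return sum(1 for f in (self.association, self.differential, self.peak_window) if f)


def select_candidates(
    association_p: Mapping[str, float] | pd.Series,
    de_classes: Mapping[str, str] | pd.Series,
    stage_expression: pd.DataFrame,
    alpha: float = 0.05,
    peak_window_dap: tuple[float, float] = (35.0, 55.0),
) -> pd.DataFrame:
    """Rank genes by the three selection criteria.

    (i) the gene's burden-association p-value is below ``alpha``;
    (ii) the gene is differentially expressed (class != unchanged);
    (iii) its arg-max expression stage falls inside ``peak_window_dap``
    (inclusive). ``stage_expression`` is genes x stages with numeric DAP
    column labels. A gene absent from an input gets an "unknown" (NA) flag
    for that criterion, never a silent False. Rank = number of satisfied
    criteria; ties break by association p-value then gene id.
    """
    assoc = pd.Series(association_p, dtype=float)
    de = pd.Series(de_classes, dtype=object)
    stages = np.asarray([float(c) for c in stage_expression.columns])

    gene_ids = sorted(
        set(assoc.index) | set(de.index) | set(stage_expression.index)
    )
    rows = []
    for gid in gene_ids:
        c1 = bool(assoc[gid] < alpha) if gid in assoc.index else None
        c2 = bool(de[gid] != "unchanged") if gid in de.index else None
        if gid in stage_expression.index:
            profile = stage_expression.loc[gid].to_numpy(dtype=float)
            peak_dap = stages[int(np.argmax(profile))]
            c3 = bool(peak_window_dap[0] <= peak_dap <= peak_window_dap[1])
        else:
            c3 = None
        flags = _CriterionFlags(c1, c2, c3)
        rows.append(
            {
                "gene": gid,
                "assoc_significant": c1,
                "differentially_expressed": c2,
                "peak_in_window": c3,
                "rank": flags.rank,
                "assoc_p": float(assoc[gid]) if gid in assoc.index else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["rank", "assoc_p", "gene"],
        ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)
    return df
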