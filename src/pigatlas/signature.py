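"""Cell-contribution statistic from signature-gene expression ratios.

For a set of genes expressed specifically by one cell type (a *signature*,
e.g. the macrophage coexpression cluster of a tissue atlas), compare a
pure population of that cell type against a composite tissue: for each
gene take the ratio of its highest expression in the pure samples to its
highest expression in the tissue samples.  If the cell type contributes a
fraction f of the tissue's mRNA, signature transcripts are diluted roughly
1/f-fold, so the mean ratio's reciprocal estimates f.  A mean ratio around
5 implies the cell type provides around 20% of the tissue's mRNA yield.
Genes far *above* the mean ratio are under-expressed in the tissue
relative to the pure population — candidate context-specific repression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix


@dataclass
class SignatureRatioResult:
    """Per-gene max-expression ratios and the implied mRNA fraction.

    ``implied_fraction`` is exactly ``1 / mean_ratio``; ``excluded`` lists
    signature genes dropped because their target maximum was zero.
    """

    ratios: pd.Series
    mean_ratio: float
    implied_fraction: float
    excluded: list[str]
    geometric: bool = False


def max_ratio_fraction(
    matrix: ExpressionMatrix,
    signature: Sequence[str],
    source_samples: Sequence[str],
    target_samples: Sequence[str],
    geometric: bool = False,
) -> SignatureRatioResult:
    """Per-gene ratio max(source) / max(target) and the implied fraction.

    ``source_samples`` are the pure cell population, ``target_samples``
    the composite tissue; the two subsets must be disjoint and non-empty.
    The mean over genes is arithmetic by default (``geometric=True``
    switches to the geometric mean, which is robust to a few extreme
    ratios).  Genes absent from the matrix are ignored; genes whose target
    maximum is zero are excluded with a warning.
    """
    if not source_samples or not target_samples:
        raise ValueError("source and target sample subsets must be non-empty")
    overlap = set(source_samples) & set(target_samples)
    if overlap:
        raise ValueError(f"source/target samples overlap: {sorted(overlap)[:5]}")
    present = [g for g in signature if g in matrix._row_index]
    if not present:
        raise ValueError("no signature gene found in the matrix")

    src = matrix.subset_samples(list(source_samples)).subset_probesets(present)
    tgt = matrix.subset_samples(list(target_samples)).subset_probesets(present)
    src_max = src.values.max(axis=1)
    tgt_max = tgt.values.max(axis=1)

    zero = tgt_max == 0
    if zero.all():
        raise ValueError("all signature genes have zero target maximum")
    excluded = [g for g, z in zip(present, zero) if z]
    if excluded:
        warnings.warn(
            f"{len(excluded)} signature gene(s) with zero target maximum excluded",
            stacklevel=2,
        )
    kept = [g for g, z in zip(present, zero) if not z]
    ratios = pd.Series(src_max[~zero] / tgt_max[~zero], index=kept, name="ratio")
    if geometric:
        mean_ratio = float(np.exp(np.log(ratios).mean()))
    else:
        mean_ratio = float(ratios.mean())
    return SignatureRatioResult(
        ratios=ratios,
        mean_ratio=mean_ratio,
        implied_fraction=1.0 / mean_ratio,
        excluded=excluded,
        geometric=geometric,
    )


def under_expressed(
    result: SignatureRatioResult, fold_cutoff: float = 2.0
) -> list[str]:
    """Signature genes under-expressed in the target relative to the mean.

    Returns genes whose ratio exceeds ``fold_cutoff`` times the mean
    ratio, sorted by descending ratio — the transcripts most strongly
    repressed in the composite tissue.
    """
    sel = result.ratios[result.ratios > fold_cutoff * result.mean_ratio]
    return list(sel.sort_values(ascending=False).index)
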