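"""Binary rank-pair encoding of DEirlncRNAs.

For a gene pair (A, B) and a sample s, the indicator C is 0 when
expr(A, s) < expr(B, s) and 1 otherwise (ties count as 1).  Because C
only compares two genes *within* a sample, it is invariant to any
per-sample rescaling — the property that lets the encoding cross
platforms without normalization.

Pairs whose indicator is 1 in almost all or almost no samples carry no
contrast; the validity filter keeps a pair only when its prevalence
(fraction of samples with C = 1) lies strictly between 20% and 80%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ValidationError

PAIR_SEP = "|"  # Ensembl-style gene IDs contain no pipes

PREV_LO = 0.2
PREV_HI = 0.8


def pair_id(gene_a: str, gene_b: str) -> str:
    """Canonical pair label: lexicographically smaller gene first."""
    a, b = sorted((gene_a, gene_b))
    return f"{a}{PAIR_SEP}{b}"


@dataclass
class PairMatrix:
    """Binary pair x sample indicator matrix.

    ``pairs`` holds canonical (geneA, geneB) tuples with geneA < geneB;
    ``C`` is a uint8 array of shape (n_pairs, n_samples).
    """

    pairs: list[tuple[str, str]]
    C: np.ndarray
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.uint8)
        if self.C.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValidationError("indicator shape mismatch")
        if not np.isin(self.C, (0, 1)).all():
            raise ValidationError("indicators must be binary")

    @property
    def pair_ids(self) -> list[str]:
        return [f"{a}{PAIR_SEP}{b}" for a, b in self.pairs]

    @property
    def prevalence(self) -> np.ndarray:
        return self.C.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=self.pair_ids, columns=self.sample_ids)

    def subset_pairs(self, pair_ids) -> "PairMatrix":
        idx = {p: i for i, p in enumerate(self.pair_ids)}
        missing = [p for p in pair_ids if p not in idx]
        if missing:
            raise ValidationError(f"pairs absent from matrix: {missing[:5]}")
        rows = [idx[p] for p in pair_ids]
        return PairMatrix([self.pairs[i] for i in rows], self.C[rows], self.sample_ids)

    def subset_samples(self, samples) -> "PairMatrix":
        pos = self.sample_ids.get_indexer(list(samples))
        if (pos < 0).any():
            raise ValidationError("unknown sample IDs")
        return PairMatrix(self.pairs, self.C[:, pos], pd.Index(list(samples)))


def encode_pairs(expr: pd.DataFrame) -> PairMatrix:
    """Enumerate all unordered gene pairs and compute their indicators.

    ``expr`` is a genes x samples DataFrame on the raw FPKM scale.  Genes
    are put in lexicographic order, every unordered pair appears once as
    (smaller, larger), and C = 1 iff expr(A) >= expr(B).
    """
    if expr.shape[0] < 2:
        raise ValidationError("need at least 2 genes to form pairs")
    if expr.shape[1] < 1:
        raise ValidationError("need at least 1 sample")
    genes = sorted(expr.index)
    X = expr.loc[genes].to_numpy()
    ia, ib = np.triu_indices(len(genes), k=1)
    C = (X[ia] >= X[ib]).astype(np.uint8)
    pairs = [(genes[i], genes[j]) for i, j in zip(ia, ib)]
    return PairMatrix(pairs, C, expr.columns)


def filter_pairs(
    pm: PairMatrix, lo: float = PREV_LO, hi: float = PREV_HI
) -> tuple[PairMatrix, int, int]:
    """Keep pairs with lo < prevalence < hi (strict on both ends).

    Returns (filtered matrix, n retained, n dropped).
    """
    if lo >= hi:
        raise ValidationError(f"invalid prevalence window: lo={lo} >= hi={hi}")
    prev = pm.prevalence
    keep = (prev > lo) & (prev < hi)
    kept = PairMatrix(
        [p for p, k in zip(pm.pairs, keep) if k], pm.C[keep], pm.sample_ids
    )
    return kept, int(keep.sum()), int((~keep).sum())
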