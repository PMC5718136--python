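"""Inter-rater agreement: weighted Cohen's kappa and its interpretation.

Validation of an automated rater against human experts on ordinal
judgements (syndrome category, per-dimension severity) uses weighted
kappa: chance-corrected agreement where a disagreement of ``d`` ordinal
steps between categories ``i`` and ``j`` is penalized by a weight
``w_ij`` — ``|i-j|/(k-1)`` (linear) or ``(i-j)^2/(k-1)^2`` (quadratic).
With observed counts ``o_ij`` and chance-expected counts
``e_ij = row_i * col_j / n``,

    kappa_w = 1 - (sum w_ij o_ij) / (sum w_ij e_ij).

The resulting value is read against the conventional Landis & Koch
bands (Poor .. Almost Perfect).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import ParseError, ValidationError

LANDIS_KOCH_BANDS = (
    # (upper bound, label); intervals are closed on the upper end, so a
    # kappa of exactly 0.80 reads Substantial and 0.81 Almost Perfect.
    (0.00, "Poor"),        # kappa < 0
    (0.20, "Slight"),      # [0.00, 0.20]
    (0.40, "Fair"),        # (0.20, 0.40]
    (0.60, "Moderate"),    # (0.40, 0.60]
    (0.80, "Substantial"),  # (0.60, 0.80]
    (1.00, "Almost Perfect"),  # (0.80, 1.00]
)


@dataclass(frozen=True)
class ContingencyTable:
    """k x k paired-rating counts over an ordered category list."""

    categories: tuple
    counts: np.ndarray  # counts[i, j] = #pairs rated (cat_i by A, cat_j by B)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise ValidationError(
                f"counts must be {k}x{k} for {k} categories, "
                f"got {counts.shape}")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValidationError("contingency table is empty (n must be > 0)")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    scheme: str
    weights: np.ndarray
    expected: np.ndarray
    band: str
    degenerate: bool = False


def contingency_from_ratings(rater_a, rater_b, categories) -> ContingencyTable:
    """Cross-tabulate two equal-length rating lists over ordered categories."""
    rater_a, rater_b = list(rater_a), list(rater_b)
    if len(rater_a) != len(rater_b):
        raise ValidationError(
            f"rating lists differ in length ({len(rater_a)} vs "
            f"{len(rater_b)})")
    if not rater_a:
        raise ValidationError("rating lists are empty (n must be > 0)")
    categories = tuple(categories)
    index = {c: i for i, c in enumerate(categories)}
    unknown = sorted({str(x) for x in rater_a + rater_b if x not in index})
    if unknown:
        raise ValidationError(
            f"label(s) not in category list: {', '.join(unknown)}")
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for a, b in zip(rater_a, rater_b):
        counts[index[a], index[b]] += 1
    return ContingencyTable(categories=categories, counts=counts)


def kappa_weights(k: int, scheme: str = "linear") -> np.ndarray:
    """Disagreement weight matrix for ``k`` ordered categories."""
    if scheme not in ("linear", "quadratic"):
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    if k < 2:
        return np.zeros((k, k))
    idx = np.arange(k)
    diff = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    return diff if scheme == "linear" else diff ** 2


def weighted_kappa(table: ContingencyTable, scheme: str = "linear",
                   ) -> KappaResult:
    """Weighted Cohen's kappa of a paired-rating contingency table.

    When both raters put all mass in one single category the expected
    disagreement is zero and kappa is undefined; such tables are
    reported with ``degenerate=True`` and kappa 1 (agreement there is
    necessarily perfect).
    """
    o = table.counts.astype(float)
    n = o.sum()
    w = kappa_weights(table.k, scheme)
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col) / n
    expected_disagreement = float((w * e).sum())
    if expected_disagreement == 0.0:
        kappa = 1.0
        degenerate = True
    else:
        kappa = 1.0 - float((w * o).sum()) / expected_disagreement
        degenerate = False
    return KappaResult(kappa=kappa, scheme=scheme, weights=w, expected=e,
                       band=interpret_kappa(kappa), degenerate=degenerate)


def interpret_kappa(kappa: float) -> str:
    """Landis & Koch qualitative band for a kappa value.

    Bands are closed on their upper boundary: < 0 Poor, [0, 0.20]
    Slight, (0.20, 0.40] Fair, (0.40, 0.60] Moderate, (0.60, 0.80]
    Substantial, (0.80, 1.00] Almost Perfect.
    """
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValidationError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.0:
        return "Poor"
    for upper, label in LANDIS_KOCH_BANDS[1:]:
        if kappa <= upper:
            return label
    return "Almost Perfect"


def read_ratings_csv(path):
    """Read paired ratings from CSV columns ``id,rater_a,rater_b``."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty ratings file") from None
        if [h.strip() for h in header] != ["id", "rater_a", "rater_b"]:
            raise ParseError(
                f"{path}: header mismatch; expected id,rater_a,rater_b")
        ids, a, b = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            ids.append(row[0].strip())
            a.append(row[1].strip())
            b.append(row[2].strip())
    return ids, a, b


def kappa_result_to_dict(result: KappaResult,
                         table: ContingencyTable) -> dict:
    """JSON-ready summary of one weighted-kappa run."""
    return {
        "kappa": result.kappa,
        "scheme": result.scheme,
        "band": result.band,
        "degenerate": result.degenerate,
        "n": table.n,
        "categories": list(table.categories),
        "counts": table.counts.tolist(),
    }
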