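"""Benchmark machinery: K_D correlation and confusion-matrix metrics.

The packaged peptide benchmark table holds the experimentally validated
NES motifs and consensus-matching non-binders used to validate the
binding-energy score: 37 peptides, 25 with measured dissociation constants
(K_D, nM) and 12 validated non-binders with no detectable binding in
pull-down assays. Scores are compared against ln K_D by ordinary least
squares; binary prediction quality is summarized by TPR/TNR, precision,
F1 and the diagnostic odds ratio, with lower score = predicted binder.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy import stats

_TABLE1_SHA256 = "270d3380cc8b0d8ce45e2d3e32ca8c6fc10e0f5098ba6d33bc8aedd379f5b64e"


@dataclass(frozen=True)
class BenchmarkEntry:
    """One benchmark peptide."""

    name: str
    sequence: str
    nes_class: Optional[str]         # None for mutants with no class
    start: int                       # first residue index in the parent protein
    phi_local: tuple[int, ...]       # annotated registry, 1-based in peptide
    kd_nM: Optional[float]
    binder: bool
    consensus_fit: bool
    engineered: bool
    expect_scan: bool


@dataclass
class ConfusionMetrics:
    """2×2 confusion counts and the derived ratios."""

    tp: int
    fp: int
    tn: int
    fn: int
    dor_infinite: bool = False

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.tpr
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @property
    def dor(self) -> float:
        if self.fp * self.fn == 0:
            return math.inf
        return (self.tp * self.tn) / (self.fp * self.fn)


def load_table1_fixture(verify: bool = True) -> list[BenchmarkEntry]:
    """Load the packaged peptide benchmark table.

    The file checksum is verified against the transcription to guard
    against accidental edits.
    """
    data = resources.files("nescan.data").joinpath("table1.tsv").read_bytes()
    if verify and hashlib.sha256(data).hexdigest() != _TABLE1_SHA256:
        raise ValueError("benchmark fixture checksum mismatch: file was modified")
    entries = []
    for line in data.decode().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, cls, start, seq, phis, kd, binder, fit, eng, expect = line.split("\t")
        entries.append(BenchmarkEntry(
            name=name,
            sequence=seq,
            nes_class=None if cls == "NA" else cls,
            start=int(start),
            phi_local=tuple(int(p) for p in phis.split(",")),
            kd_nM=None if kd == "NA" else float(kd),
            binder=binder == "1",
            consensus_fit=fit == "1",
            engineered=eng == "1",
            expect_scan=expect == "1",
        ))
    return entries


def correlate_lnkd(
    scores: Sequence[float], kd_values_nM: Sequence[float]
) -> tuple[float, float, float, float, float]:
    """OLS of ln K_D on the score: (r, r², p, slope, intercept).

    Natural log. Requires ≥3 pairs, positive K_D and non-degenerate inputs.
    """
    x = np.asarray(scores, dtype=float)
    kd = np.asarray(kd_values_nM, dtype=float)
    if len(x) != len(kd) or len(x) < 3:
        raise ValueError("need ≥3 paired (score, K_D) observations")
    if np.any(kd <= 0):
        raise ValueError("K_D values must be positive")
    y = np.log(kd)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or lnK_D")
    fit = stats.linregress(x, y)
    return (float(fit.rvalue), float(fit.rvalue ** 2), float(fit.pvalue),
            float(fit.slope), float(fit.intercept))


def confusion(
    scores: Sequence[float], labels: Sequence[bool], threshold: float
) -> ConfusionMetrics:
    """Confusion metrics at one score cut; score ≤ threshold predicts binder."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(s) != len(y):
        raise ValueError("scores/labels length mismatch")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    pred = s <= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                            dor_infinite=(fp * fn == 0))


def sweep_threshold(
    scores: Sequence[float], labels: Sequence[bool]
) -> list[tuple[float, ConfusionMetrics]]:
    """Metrics at every distinct score value used as the cut."""
    y = np.asarray(labels, dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValueError("need at least one positive and one negative")
    cuts = sorted(set(float(s) for s in scores))
    return [(c, confusion(scores, labels, c)) for c in cuts]
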