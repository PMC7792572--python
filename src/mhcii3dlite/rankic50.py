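"""Binding rank and IC50 estimation.

Raw threading scores live on an arbitrary energy scale, so they are
normalised against a background peptide set: the binding rank of a
query is the normalised Wilcoxon-Mann-Whitney statistic of its score
against the background scores (fraction of background scoring strictly
better, ties at half weight).  Rank 0 marks the strongest binder,
rank 1 the weakest.

Ranks are mapped to IC50 estimates through a linear model on the
saturating log transform y = 1 - log(IC50)/log(50000):

    IC50_pred = 50000 ** (1 - (slope * rank + intercept))

with default coefficients slope = -0.4265748, intercept = 0.51225
obtained by regressing transformed experimental IC50 values on binding
ranks.  Peptides with predicted IC50 below 500 nM are classified as
binders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import InputError, ParameterError

#: IC50 saturation constant, nM
SATURATION_NM = 50_000.0
#: binder/non-binder IC50 cutoff, nM
BINDER_CUTOFF_NM = 500.0
#: default linear-model coefficients (transformed IC50 on binding rank)
DEFAULT_SLOPE = -0.4265748
DEFAULT_INTERCEPT = 0.51225


@dataclass
class BackgroundSet:
    """Background peptides with their cached binding scores."""

    peptides: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.peptides) != len(self.scores):
            raise ParameterError("peptides/scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ParameterError("background scores must be finite")

    @property
    def size(self) -> int:
        return len(self.scores)

    @classmethod
    def from_peptides(cls, peptides: Iterable[str], scaffolds, ssf) -> "BackgroundSet":
        from .threading import background_scores

        peptides = list(peptides)
        return cls(peptides, background_scores(peptides, scaffolds, ssf))


@dataclass
class IC50Model:
    """Linear model from binding rank to transformed IC50."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    saturation: float = SATURATION_NM
    transform: str = "one-minus-log-ratio"

    def __post_init__(self) -> None:
        if self.saturation <= 0:
            raise ParameterError("saturation must be positive")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            f"slope {self.slope!r}\nintercept {self.intercept!r}\n"
            f"saturation {self.saturation!r}\ntransform {self.transform}\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "IC50Model":
        fields = dict(
            line.split(None, 1) for line in Path(path).read_text().splitlines() if line
        )
        return cls(
            slope=float(fields["slope"]),
            intercept=float(fields["intercept"]),
            saturation=float(fields["saturation"]),
            transform=fields.get("transform", "one-minus-log-ratio").strip(),
        )


def binding_rank(score: float, background_scores: Sequence[float]) -> float:
    """Normalised WMW rank of a score against background scores.

    rank = (#background strictly lower + 0.5 * #ties) / N; lower energy
    is better, so rank 0 means the query beats the whole background.
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise InputError("background set is empty")
    better = np.count_nonzero(bg < score)
    ties = np.count_nonzero(bg == score)
    return float((better + 0.5 * ties) / bg.size)


def ic50_transform(ic50: float | np.ndarray) -> float | np.ndarray:
    """Saturating log transform y = 1 - log(IC50)/log(50000), clamped to [0, 1]."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise InputError("IC50 must be positive")
    y = 1.0 - np.log(np.minimum(ic50, SATURATION_NM)) / np.log(SATURATION_NM)
    y = np.minimum(y, 1.0)  # IC50 < 1 nM clamps to 1
    return float(y) if y.ndim == 0 else y


def fit_ic50_model(pairs: Iterable[tuple[float, float]]) -> IC50Model:
    """Ordinary least squares of transformed IC50 on binding rank."""
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise InputError("need at least two (rank, ic50) pairs")
    ranks, ic50s = data[:, 0], data[:, 1]
    if np.allclose(ranks, ranks[0]):
        raise InputError("degenerate fit: all ranks identical")
    y = ic50_transform(ic50s)
    fit = stats.linregress(ranks, y)
    return IC50Model(slope=float(fit.slope), intercept=float(fit.intercept))


def predict_ic50(model: IC50Model, rank: float) -> float:
    """IC50 estimate (nM) for a binding rank in [0, 1], capped at saturation."""
    if not 0.0 <= rank <= 1.0:
        raise InputError(f"rank {rank} outside [0, 1]")
    ic50 = model.saturation ** (1.0 - (model.slope * rank + model.intercept))
    return float(min(ic50, model.saturation))


def binder_cutoff_rank(model: IC50Model, cutoff_nm: float = BINDER_CUTOFF_NM) -> float:
    """Rank at which the predicted IC50 crosses the binder cutoff (closed form)."""
    y = 1.0 - np.log(cutoff_nm) / np.log(model.saturation)
    return float((y - model.intercept) / model.slope)


def classify(ic50: float, cutoff: float = BINDER_CUTOFF_NM) -> str:
    """Binder iff IC50 strictly below the cutoff."""
    if ic50 <= 0:
        raise InputError("IC50 must be positive")
    return "binder" if ic50 < cutoff else "non_binder"
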