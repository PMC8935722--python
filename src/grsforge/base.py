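"""Shared model contract: anything with ``predict_risk`` mapping genotypes to [0, 1]."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .genotype_data import SNPMatrix

__all__ = ["GRSModel", "ConstantGRS", "genotype_values"]


def genotype_values(genotypes) -> np.ndarray:
    """Accept an SNPMatrix or a bare array and return the value matrix."""
    if isinstance(genotypes, SNPMatrix):
        return genotypes.values
    return np.asarray(genotypes)


@runtime_checkable
class GRSModel(Protocol):
    """Fitted genetic risk score: genotypes -> per-sample case probabilities."""

    def predict_risk(self, genotypes) -> np.ndarray: ...


@dataclass
class ConstantGRS:
    """Uninformative score predicting one fixed probability (e.g. the prevalence)."""

    value: float

    def predict_risk(self, genotypes) -> np.ndarray:
        n = genotype_values(genotypes).shape[0]
        return np.full(n, self.value, dtype=float)
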