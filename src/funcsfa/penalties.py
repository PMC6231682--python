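"""Elastic-net penalty configuration shared by the EM core and model selection.

Each data type gets one nonnegative penalty level ``l``; with mixing
parameter ``alpha`` in (0, 1] the per-feature penalties are

    lambda_1 = alpha * l_datatype(j)
    lambda_2 = 1e-6 + (1 - alpha) * l_datatype(j)

so all features of one data type share identical penalties.  The 1e-6
floor on lambda_2 keeps the ridge part strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

RIDGE_FLOOR = 1e-6

__all__ = ["PenaltyConfig", "expand_penalties", "RIDGE_FLOOR"]


@dataclass(frozen=True)
class PenaltyConfig:
    alpha: float
    levels: tuple[float, ...]  # one nonnegative level per data type

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")
        object.__setattr__(self, "levels", tuple(float(l) for l in self.levels))
        if any(l < 0 for l in self.levels):
            raise ValidationError("penalty levels must be nonnegative")

    @property
    def n_types(self) -> int:
        return len(self.levels)

    def lambda1_per_type(self) -> np.ndarray:
        return self.alpha * np.asarray(self.levels)

    def lambda2_per_type(self) -> np.ndarray:
        return RIDGE_FLOOR + (1.0 - self.alpha) * np.asarray(self.levels)

    def per_feature(self, datatype_of_feature: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
        """(lambda_1, lambda_2) arrays over the stacked feature axis."""
        d = np.asarray(datatype_of_feature, dtype=int)
        if d.size and d.max() >= self.n_types:
            raise ValidationError("datatype index exceeds configured levels")
        return self.lambda1_per_type()[d], self.lambda2_per_type()[d]

    @classmethod
    def zero(cls, n_types: int, alpha: float = 0.9) -> "PenaltyConfig":
        return cls(alpha=alpha, levels=(0.0,) * n_types)


def expand_penalties(alpha: float, levels) -> PenaltyConfig:
    """Build a :class:`PenaltyConfig` from the mixing parameter and
    per-data-type levels."""
    return PenaltyConfig(alpha=alpha, levels=tuple(np.atleast_1d(levels)))
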