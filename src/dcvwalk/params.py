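"""Shared parameters of the heterogeneous random-walk transport model.

The model describes a cargo (a dense-core vesicle) that every ``step_time_s``
seconds either advances by one lattice step of ``step_size_um`` micrometres
(probability ``p``) or stays put (probability ``1 - p``).  Heterogeneity across
the vesicle population enters through ``p`` itself being random, drawn once per
trajectory from a Beta(``alpha``, ``beta``) density.  The four constants in
:class:`ModelParams` are shared by every distribution, the simulator, and the
fitting code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

__all__ = ["ModelParams", "DEFAULT_STEP_SIZE_UM", "DEFAULT_STEP_TIME_S"]

#: Camera pixel size in micrometres; one lattice step spans one pixel.
DEFAULT_STEP_SIZE_UM = 0.092
#: Elementary step time in seconds (one tenth of the 0.1563 s frame interval).
DEFAULT_STEP_TIME_S = 0.01563


@dataclass(frozen=True)
class ModelParams:
    """Constants of the heterogeneous random walk.

    Parameters
    ----------
    alpha, beta
        Shape parameters of the beta density of the per-track movement
        probability ``p``.  ``alpha`` measures the propensity for successful
        movement, ``beta`` the degree of failure (immobilization); both must
        be strictly positive.
    step_size_um
        Lattice step ``a`` in micrometres.
    step_time_s
        Step duration ``tau`` in seconds.
    """

    alpha: float
    beta: float
    step_size_um: float = DEFAULT_STEP_SIZE_UM
    step_time_s: float = DEFAULT_STEP_TIME_S

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta-density shapes must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )
        if not (self.step_size_um > 0 and self.step_time_s > 0):
            raise ValueError("step_size_um and step_time_s must be positive")

    @property
    def mean_p(self) -> float:
        """Mean movement probability ``alpha / (alpha + beta)``."""
        return self.alpha / (self.alpha + self.beta)

    def n_steps(self, t_seconds: float, *, rtol: float = 1e-6) -> int:
        """Number of elementary steps ``n = t / tau`` for an elapsed time.

        ``t_seconds`` must be a non-negative integer multiple of the step time
        (within ``rtol``); e.g. t = 1.563 s with the default tau gives n = 100.
        """
        if t_seconds < 0:
            raise ValueError(f"elapsed time must be non-negative, got {t_seconds}")
        ratio = t_seconds / self.step_time_s
        n = round(ratio)
        if abs(ratio - n) > rtol * max(1.0, abs(ratio)):
            raise ValueError(
                f"t={t_seconds} s is not an integer multiple of tau="
                f"{self.step_time_s} s"
            )
        return int(n)

    def k_steps(self, distance_um: float, *, rtol: float = 1e-6) -> int:
        """Number of lattice steps ``k = z / a`` for a distance in µm."""
        if distance_um < 0:
            raise ValueError(f"distance must be non-negative, got {distance_um}")
        ratio = distance_um / self.step_size_um
        k = round(ratio)
        if abs(ratio - k) > rtol * max(1.0, abs(ratio)):
            raise ValueError(
                f"z={distance_um} µm is not an integer multiple of a="
                f"{self.step_size_um} µm"
            )
        return int(k)

    def with_shapes(self, alpha: float, beta: float) -> "ModelParams":
        """Copy of these parameters with new beta-density shapes."""
        return replace(self, alpha=alpha, beta=beta)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "step_size_um": self.step_size_um,
            "step_time_s": self.step_time_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            step_size_um=float(d.get("step_size_um", DEFAULT_STEP_SIZE_UM)),
            step_time_s=float(d.get("step_time_s", DEFAULT_STEP_TIME_S)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))
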