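"""Run configuration shared by all reconstruction stages.

The defaults are the reference parameterization of the method: grid spacing
``delta1``, level-descent step ``delta2``, jump multiplier ``m``, low-energy
detail cutoff ``c0`` (energy above the global grid minimum below which full
detail is kept), small-basin pruning threshold ``n0``, alpha-shape parameter
``alpha``, neighbor-basin vertex-distance threshold ``d_th = 20 * alpha``,
kernel bandwidth ``h``, reduced-gradient step length ``p``, leader-clustering
radius ``eps`` and gradient-zero tolerance ``eps_g``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

KERNELS = ("gaussian", "epanechnikov", "tricube", "bounded_gaussian")
#: kernels with continuous first and second derivatives, usable for
#: gradient/Hessian evaluation (saddle search, Newton descent)
SMOOTH_KERNELS = ("gaussian", "bounded_gaussian")

RGF_MODES = ("predictor_corrector", "combined")


@dataclass
class RunConfig:
    """Parameters controlling smoothing, BDR and SDR reconstruction."""

    delta1: float = 0.1      # grid spacing (PC units)
    delta2: float = 0.3      # BDR level-descent step (energy units)
    m: int = 50              # BDR jump multiplier
    c0: float = 200.0        # detail cutoff above the global grid minimum
    n0: int = 100            # minimum basin grid-point count above the cutoff
    alpha: float = 0.15      # alpha-convex shape parameter (ball radius 1/alpha)
    d_th: float | None = None  # neighbor-basin distance threshold; 20*alpha if None
    h: float = 0.7           # kernel regression bandwidth (PC units)
    p: float = 0.1           # RGF predictor step length
    eps: float = 0.01        # leader-clustering radius
    eps_g: float = 0.001     # gradient-zero tolerance
    kernel: str = "gaussian"
    seed: int = 0

    # numerical realization knobs (not part of the core parameter set)
    jitter: float | None = None        # saddle jitter magnitude; 2*delta1 if None
    rgf_mode: str = "predictor_corrector"
    max_curve_steps: int = 10000       # cap per reduced-gradient curve
    max_trace_steps: int = 10000       # cap per basin-boundary trace

    def __post_init__(self) -> None:
        if self.d_th is None:
            self.d_th = 20.0 * self.alpha
        if self.jitter is None:
            self.jitter = 2.0 * self.delta1
        for name in ("delta1", "delta2", "c0", "alpha", "d_th", "h", "p",
                     "eps", "eps_g", "jitter"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"RunConfig.{name} must be strictly positive, got {value!r}")
        for name in ("m", "n0", "max_curve_steps", "max_trace_steps"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"RunConfig.{name} must be a positive integer")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
        if self.rgf_mode not in RGF_MODES:
            raise ValueError(f"unknown rgf_mode {self.rgf_mode!r}; choose from {RGF_MODES}")

    def replace(self, **kwargs) -> "RunConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)
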