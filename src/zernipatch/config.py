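"""Run configuration shared by the pipeline and the CLI.

Every output file embeds the serialized configuration so a run can be
reproduced bit-for-bit from its artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .errors import ConfigError


@dataclass
class RunConfig:
    """Tunable parameters of the patch-description pipeline.

    order
        Truncation order N of the Zernike expansion (121 invariants at 20).
    dim
        Voxel-grid edge length; 64 resolves order-20 polynomials.
    ball_fill
        Radius at which the farthest surface point is placed inside the unit
        ball, avoiding truncation at the boundary.
    probe_radius
        Solvent probe radius in Angstrom (1.4 ~ water).
    dielectric
        Uniform dielectric constant dividing the Coulomb sum.
    samples_per_atom
        Fibonacci-lattice samples per expanded atom sphere.
    normalize_descriptors
        Scale each invariant vector to unit L2 length before comparison.
    binarize_elec
        Use 0/1 occupancy instead of |potential| weights in the electrostatic
        channels.
    """

    order: int = 20
    dim: int = 64
    ball_fill: float = 0.7
    probe_radius: float = 1.4
    dielectric: float = 4.0
    samples_per_atom: int = 200
    normalize_descriptors: bool = False
    binarize_elec: bool = False

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ConfigError("order must be nonnegative")
        if self.dim < 16:
            raise ConfigError("dim must be at least 16")
        if not (0.0 < self.ball_fill < 1.0):
            raise ConfigError("ball_fill must lie in (0, 1)")
        if self.probe_radius < 0:
            raise ConfigError("probe_radius must be nonnegative")
        if self.dielectric <= 0:
            raise ConfigError("dielectric must be positive")
        if self.samples_per_atom < 12:
            raise ConfigError("samples_per_atom must be at least 12")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())
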