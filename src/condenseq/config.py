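"""Experiment configuration: defaults, validation, YAML round-trip.

Defaults are the full-scale study conditions: a 500-monomer chain in an
80 x 80 x 600 sigma box, Langevin thermostat at T = 1 kBT with damping
0.1 / tau, time step 0.01 tau, and a production run of 1.5e7 steps saving
3000 frames.  Desk-scale work uses :func:`scaled_config`, which shrinks the
chain and box proportionally and shortens the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .units import concentration_to_count, count_to_concentration, SIGMA_NM


class ConfigError(ValueError):
    """Invalid or unknown configuration value."""


@dataclass
class ExperimentConfig:
    """All knobs of one simulation run, in reduced units unless noted."""

    model: str = "homogeneous"
    n_monomers: int = 500
    box: tuple[float, float, float] = (80.0, 80.0, 600.0)
    re_prime: float = 0.6          # tether separation / contour length
    rho_p_um: float = 84.50        # bulk protein concentration, uM
    n_proteins: int | None = None  # overrides rho_p_um when set
    eps_pp: float = 2.0            # protein-protein attraction, kBT
    eps_mp_scale: float = 1.0      # multiplier on the affinity profile
    temperature: float = 1.0       # kBT
    gamma: float = 0.1             # damping, 1/tau
    dt: float = 0.01               # tau
    kb: float = 100.0              # harmonic bond constant, kBT/sigma^2
    lp_monomers: float = 15.0      # persistence length -> kappa = lp * kBT
    bond_length: float = 1.0       # sigma
    sigma_nm: float = SIGMA_NM
    protein_near_chain_fraction: float = 0.0  # placed within reach of the chain
    dna_equil_steps: int = 100_000
    equil_steps: int = 2_000_000
    production_steps: int = 15_000_000
    n_frames: int = 3000
    seed: int = 1

    # -- derived quantities -------------------------------------------------

    @property
    def contour_length(self) -> float:
        """Chain contour length s = (Nm - 1) * bond_length, sigma."""
        return (self.n_monomers - 1) * self.bond_length

    @property
    def tether_separation(self) -> float:
        """Re = Re' * s, sigma."""
        return self.re_prime * self.contour_length

    @property
    def kappa(self) -> float:
        """Bending constant kappa = lp (in bonds) x kBT, giving the target
        persistence length for the discrete worm-like chain."""
        return self.lp_monomers * self.temperature

    @property
    def protein_count(self) -> int:
        if self.n_proteins is not None:
            return self.n_proteins
        return concentration_to_count(self.rho_p_um, self.box, self.sigma_nm)

    @property
    def effective_rho_um(self) -> float:
        return count_to_concentration(self.protein_count, self.box, self.sigma_nm)

    @property
    def save_interval(self) -> int:
        return self.production_steps // self.n_frames

    def __post_init__(self) -> None:
        self.box = tuple(float(x) for x in self.box)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.re_prime <= 1:
            raise ConfigError(f"re_prime must be in (0, 1], got {self.re_prime}")
        if self.n_monomers < 3:
            raise ConfigError(f"need at least 3 monomers, got {self.n_monomers}")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ConfigError(f"box must be 3 positive lengths, got {self.box}")
        if self.tether_separation > self.box[2]:
            raise ConfigError(
                f"tether separation {self.tether_separation:.1f} exceeds box long axis {self.box[2]}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if self.rho_p_um < 0:
            raise ConfigError(f"rho_p_um must be non-negative, got {self.rho_p_um}")
        if self.n_proteins is not None and self.n_proteins < 0:
            raise ConfigError(f"n_proteins must be non-negative, got {self.n_proteins}")
        if not 0 <= self.protein_near_chain_fraction <= 1:
            raise ConfigError("protein_near_chain_fraction must be in [0, 1]")
        if self.n_frames < 1 or self.production_steps < 1:
            raise ConfigError("production_steps and n_frames must be positive")
        if self.production_steps % self.n_frames != 0:
            raise ConfigError(
                f"n_frames ({self.n_frames}) must divide production_steps "
                f"({self.production_steps})")
        for name in ("temperature", "gamma", "kb", "bond_length", "sigma_nm"):
            if getattr(self, name) < 0 or (name != "temperature" and getattr(self, name) == 0):
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

    # -- provenance ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = list(self.box)
        return d

    def config_hash(self) -> str:
        """Short digest identifying the full parameter set."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "box" in data:
            data = dict(data)
            data["box"] = tuple(data["box"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def scaled_config(model: str = "homogeneous", n_monomers: int = 50,
                  re_prime: float = 0.6, rho_p_um: float = 84.50,
                  seed: int = 1, **overrides) -> ExperimentConfig:
    """Desk-scale preset: chain, box, and run length shrunk proportionally.

    The box cross-section scales with the chain so the protein count at a
    given concentration stays manageable; block layouts scale through
    :func:`condenseq.affinity.build_block_profile`.
    """
    frac = n_monomers / 500
    box = (max(16.0, 80.0 * frac ** 0.5),
           max(16.0, 80.0 * frac ** 0.5),
           max(40.0, 600.0 * frac))
    # keep z long enough for the tether and some bulk
    box = (box[0], box[1], max(box[2], 1.4 * re_prime * (n_monomers - 1)))
    defaults = dict(
        model=model, n_monomers=n_monomers, box=box, re_prime=re_prime,
        rho_p_um=rho_p_um, dna_equil_steps=30_000, equil_steps=150_000,
        production_steps=150_000, n_frames=300, seed=seed,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@dataclass
class ScanSpec:
    """A grid experiment over Re' and/or protein concentration."""

    model: str = "het1"
    re_prime_grid: tuple[float, ...] = (0.6,)
    rho_grid_um: tuple[float, ...] = (84.50,)
    replicates: int = 5
    base: ExperimentConfig = field(default_factory=ExperimentConfig)

    def __post_init__(self) -> None:
        self.re_prime_grid = tuple(float(x) for x in self.re_prime_grid)
        self.rho_grid_um = tuple(float(x) for x in self.rho_grid_um)
        if not self.re_prime_grid or not self.rho_grid_um:
            raise ConfigError("scan grids must be non-empty")
        if self.replicates < 1:
            raise ConfigError("need at least one replicate")
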