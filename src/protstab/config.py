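"""Runtime configuration: every tunable constant of the pipeline in one place.

Defaults can be overridden from a YAML file (``Config.from_yaml``) or
programmatically.  The configuration hash is embedded in saved model bundles
so that a prediction is reproducible only together with the feature settings
it was trained under.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

# Van der Waals radii (A) used by the solvent-accessibility calculation.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}

# Maximum accessible surface area (A^2) per residue in an extended Gly-X-Gly
# tripeptide (theoretical values of Tien et al. 2013); denominators for RSA.
DEFAULT_MAX_ACC: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class SasaConfig:
    probe_radius: float = 1.4          # A, water probe
    # lattice points per atom: binary sphere sampling converges ~ n^-1/2, and
    # this density keeps per-residue areas stable to <0.5% under rigid motion
    n_sphere_points: int = 7680
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    max_acc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MAX_ACC))


@dataclass
class SecondaryStructureConfig:
    # phi/psi windows in degrees; a run of >= min_run residues inside the
    # window is required before the class is assigned.
    helix_phi: tuple[float, float] = (-120.0, -30.0)
    helix_psi: tuple[float, float] = (-80.0, -5.0)
    strand_phi: tuple[float, float] = (-180.0, -45.0)
    strand_psi: tuple[float, float] = (45.0, 180.0)
    strand_psi_wrap: tuple[float, float] = (-180.0, -170.0)
    helix_min_run: int = 3
    strand_min_run: int = 2


@dataclass
class CsmConfig:
    d_min: float = 0.0                 # A, first distance cutoff
    d_max: float = 10.0                # A, last distance cutoff
    step: float = 0.5                  # A, cutoff increment
    environment_radius: float = 10.0   # A, residue-environment inclusion radius


@dataclass
class SdmConfig:
    rsa_buried: float = 0.07           # rsa <  buried  -> buried
    rsa_exposed: float = 0.25          # rsa >= exposed -> exposed
    pseudocount: float = 1.0
    scale: float = 1.0                 # kcal/mol per log-unit of propensity ratio
    tree_min_leaf: int = 20
    tree_max_depth: int = 4
    tree_sd_stop: float = 0.05         # stop when SD reduction < 5% of root SD


@dataclass
class SvrConfig:
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    epsilon_grid: tuple[float, ...] = (0.1,)
    cv_folds: int = 5
    cv_seed: int = 17                  # fold shuffling seed, recorded in bundles
    stack_folds: int = 5               # out-of-fold stacking for the consensus


@dataclass
class Config:
    sasa: SasaConfig = field(default_factory=SasaConfig)
    ss: SecondaryStructureConfig = field(default_factory=SecondaryStructureConfig)
    csm: CsmConfig = field(default_factory=CsmConfig)
    sdm: SdmConfig = field(default_factory=SdmConfig)
    svr: SvrConfig = field(default_factory=SvrConfig)
    hbond_cutoff: float = 3.5          # A, heavy-atom donor/acceptor distance
    # 'negative_destabilizing': ddG < 0 means the mutation destabilizes.
    sign_convention: str = "negative_destabilizing"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        cfg = cls()
        for section, value in d.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section}")
            current = getattr(cfg, section)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                for k, v in value.items():
                    if not hasattr(current, k):
                        raise KeyError(f"unknown config key: {section}.{k}")
                    default = getattr(current, k)
                    if isinstance(default, tuple) and isinstance(v, (list, tuple)):
                        v = tuple(v)
                    setattr(current, k, v)
            else:
                setattr(cfg, section, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
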