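"""Parameter containers for the receptor-complex ensemble model.

All energies are in units of the thermal energy kT; all ligand
concentrations are in mM.  Expression levels of the adapter protein CheW
and the kinase CheA are expressed as multiples ``i`` and ``j`` of their
wild-type levels, entering the per-molecule incorporation energies as
``mu(i) = mu0 - ln i`` (a potential that decreases as the protein becomes
more abundant).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "LinkerScheme",
    "ModificationState",
    "LigandBinding",
    "ExpressionCondition",
    "EnsembleParameters",
    "load_parameters",
    "dump_parameters",
]


class LinkerScheme(str, Enum):
    """Connectivity variants for the inter-trimer linkers.

    BRIDGED
        The base architecture: two trimers of dimers are bridged by a
        -CheW-CheA2-CheW- unit, CheA2 acting purely as a bridge
        (per-linker energy ``mu_a2 + 2 mu_w``).
    BRIDGED_PLUS_WONLY
        Adds the CheW-only linker -CheW-CheW2-CheW- observed by electron
        cryotomography (per-linker energy ``mu_w2 + 2 mu_w``); complexes
        may mix the two linker types.
    SYMMETRIC
        Alternative architecture in which CheA monomers contact the
        trimers directly, making CheA and CheW symmetric
        (per-linker energy ``2 mu_a + 2 mu_w`` with ``mu_a`` a monomer
        potential).
    SYMMETRIC_PLUS_WONLY
        The symmetric architecture with CheW-only linkers added.
    """

    BRIDGED = "BRIDGED"
    BRIDGED_PLUS_WONLY = "BRIDGED_PLUS_WONLY"
    SYMMETRIC = "SYMMETRIC"
    SYMMETRIC_PLUS_WONLY = "SYMMETRIC_PLUS_WONLY"

    @property
    def has_wonly(self) -> bool:
        return self in (
            LinkerScheme.BRIDGED_PLUS_WONLY,
            LinkerScheme.SYMMETRIC_PLUS_WONLY,
        )

    @property
    def symmetric(self) -> bool:
        return self in (
            LinkerScheme.SYMMETRIC,
            LinkerScheme.SYMMETRIC_PLUS_WONLY,
        )

    @property
    def base(self) -> "LinkerScheme":
        """The scheme with CheW-only linkers removed."""
        return LinkerScheme.SYMMETRIC if self.symmetric else LinkerScheme.BRIDGED


@dataclass(frozen=True)
class ModificationState:
    """Receptor modification (methylation-mimicking QE pattern).

    ``delta_eps`` is the free-energy offset (kT) favouring the active
    conformation at zero ligand; it is negative for the attractant
    responses modelled here.
    """

    delta_eps: float
    label: str = "QEQE"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_eps):
            raise ValueError("delta_eps must be finite")


@dataclass(frozen=True)
class LigandBinding:
    """Conformation-dependent ligand dissociation constants (mM).

    The inactive state binds attractant more tightly, so ``kd_on`` (the
    active-state constant) must exceed ``kd_off``.
    """

    kd_on: float
    kd_off: float

    def __post_init__(self) -> None:
        if not (self.kd_off > 0 and self.kd_on > 0):
            raise ValueError("dissociation constants must be positive")
        if not self.kd_on > self.kd_off:
            raise ValueError("kd_on must exceed kd_off (inactive state binds tighter)")


@dataclass(frozen=True)
class ExpressionCondition:
    """CheW / CheA expression levels as multiples of wild type.

    ``a_mult = 0`` is the CheA-deletion limit: every CheA-containing
    species receives zero statistical weight.
    """

    w_mult: float = 1.0
    a_mult: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.w_mult > 0:
            raise ValueError("w_mult must be positive")
        if self.a_mult < 0:
            raise ValueError("a_mult must be nonnegative")


@dataclass(frozen=True)
class EnsembleParameters:
    """All thermodynamic parameters of one model variant.

    Parameters
    ----------
    mod : ModificationState
        Receptor modification state (activity offset ``delta_eps``).
    binding : LigandBinding
        Ligand dissociation constants of the two conformations.
    j_coupling : float
        Coupling energy J (kT) awarded per linker in an *active* complex;
        J < 0 favours active clustering.
    mu_w0, mu_a2_0 : float
        Wild-type incorporation potentials (kT) for one CheW monomer and
        one CheA2 dimer (under symmetric schemes ``mu_a2_0`` stores the
        CheA *monomer* potential).
    mu_w2_0 : float or None
        Wild-type potential of the central CheW2 unit of a CheW-only
        linker; ``None`` defaults to ``2 * mu_w0`` for symmetric schemes
        and is required for BRIDGED_PLUS_WONLY.
    rho_target : float
        Target mean receptor-dimer density per membrane site (the
        constant average complex size enforced by the chemical potential).
    x_max : int
        Maximal number of connected trimers of dimers per complex.
    scheme : LinkerScheme
        Linker architecture variant.
    """

    mod: ModificationState
    binding: LigandBinding
    j_coupling: float
    mu_w0: float
    mu_a2_0: float
    rho_target: float
    mu_w2_0: float | None = None
    x_max: int = 4
    scheme: LinkerScheme = LinkerScheme.BRIDGED

    def __post_init__(self) -> None:
        if self.x_max < 1:
            raise ValueError("x_max must be at least 1")
        if not (0 < self.rho_target < 3 * self.x_max):
            raise ValueError(
                f"rho_target must lie in (0, {3 * self.x_max}) for x_max={self.x_max}"
            )
        if (
            self.scheme is LinkerScheme.BRIDGED_PLUS_WONLY
            and self.mu_w2_0 is None
        ):
            raise ValueError("mu_w2_0 is required for the BRIDGED_PLUS_WONLY scheme")

    def replace(self, **changes: Any) -> "EnsembleParameters":
        """Return a copy with the given flat or nested fields replaced.

        Accepts both dataclass field names (``j_coupling``) and the flat
        config keys (``J``, ``delta_eps``, ``kd_on`` ...).
        """
        flat = {
            "delta_eps": lambda v: {"mod": replace(self.mod, delta_eps=float(v))},
            "kd_on": lambda v: {"binding": replace(self.binding, kd_on=float(v))},
            "kd_off": lambda v: {"binding": replace(self.binding, kd_off=float(v))},
            "J": lambda v: {"j_coupling": float(v)},
            "rho": lambda v: {"rho_target": float(v)},
        }
        out: dict[str, Any] = {}
        binding_changes: dict[str, float] = {}
        for key, value in changes.items():
            if key in ("kd_on", "kd_off"):
                binding_changes[key] = float(value)
            elif key in flat:
                out.update(flat[key](value))
            else:
                out[key] = value
        if binding_changes:
            out["binding"] = replace(self.binding, **binding_changes)
        return replace(self, **out)

    def get(self, name: str) -> float:
        """Look up a parameter by its flat config key or field name."""
        aliases = {
            "delta_eps": self.mod.delta_eps,
            "kd_on": self.binding.kd_on,
            "kd_off": self.binding.kd_off,
            "J": self.j_coupling,
            "rho": self.rho_target,
        }
        if name in aliases:
            return aliases[name]
        return getattr(self, name)

    def to_dict(self) -> dict[str, Any]:
        d = {
            "delta_eps": self.mod.delta_eps,
            "kd_on": self.binding.kd_on,
            "kd_off": self.binding.kd_off,
            "J": self.j_coupling,
            "mu_w0": self.mu_w0,
            "mu_a2_0": self.mu_a2_0,
            "rho": self.rho_target,
            "x_max": self.x_max,
            "scheme": self.scheme.value,
        }
        if self.mu_w2_0 is not None:
            d["mu_w2_0"] = self.mu_w2_0
        if self.mod.label:
            d["label"] = self.mod.label
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EnsembleParameters":
        """Build parameters from a flat mapping (the config-file schema).

        Required keys: delta_eps, kd_on, kd_off, J, mu_w0, mu_a2_0, rho.
        Optional: mu_w2_0, x_max (default 4), scheme (default BRIDGED),
        label.
        """
        required = ["delta_eps", "kd_on", "kd_off", "J", "mu_w0", "mu_a2_0", "rho"]
        missing = [k for k in required if k not in d]
        if missing:
            raise KeyError(
                "missing required parameter key(s): " + ", ".join(sorted(missing))
            )
        known = set(required) | {"mu_w2_0", "x_max", "scheme", "label"}
        unknown = sorted(set(d) - known)
        if unknown:
            raise KeyError("unknown parameter key(s): " + ", ".join(unknown))
        scheme = LinkerScheme(str(d.get("scheme", "BRIDGED")))
        mu_w2_0 = d.get("mu_w2_0")
        return cls(
            mod=ModificationState(
                delta_eps=float(d["delta_eps"]), label=str(d.get("label", "QEQE"))
            ),
            binding=LigandBinding(kd_on=float(d["kd_on"]), kd_off=float(d["kd_off"])),
            j_coupling=float(d["J"]),
            mu_w0=float(d["mu_w0"]),
            mu_a2_0=float(d["mu_a2_0"]),
            rho_target=float(d["rho"]),
            mu_w2_0=None if mu_w2_0 is None else float(mu_w2_0),
            x_max=int(d.get("x_max", 4)),
            scheme=scheme,
        )


def load_parameters(path: str | Path) -> EnsembleParameters:
    """Read an :class:`EnsembleParameters` from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} does not contain a mapping")
    return EnsembleParameters.from_dict(data)


def dump_parameters(params: EnsembleParameters, path: str | Path) -> None:
    """Write parameters to JSON or YAML, chosen by file extension."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
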