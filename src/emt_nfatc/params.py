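"""Kinetic parameters for the mechanistic EMT-NFATc ODE model.

Units are molecules and hours throughout.  Production rates ``g`` are
molecules/h except for ZEB protein, whose ``g`` is a per-mRNA translation
rate (1/h); degradation rates ``k`` are 1/h; the SNAIL input ``S`` is a
clamped molecule count.

Regulation comes in two flavours:

* a shifted Hill factor ``H = (1 + lam*(x/A0)^n) / (1 + (x/A0)^n)`` per
  transcriptional/indirect edge — equal to 1 with no regulator, ``lam``
  at saturation (``lam > 1`` activation, ``lam < 1`` inhibition);
* a microRNA binding-site block for the miR-200 -> ZEB-mRNA edge, where
  occupancy of ``n_sites`` sites modulates translation (``l`` vector),
  mRNA active degradation (``gamma_m``) and microRNA co-degradation
  (``gamma_mu``).

The shipped default numbers start from the published core miR-200/ZEB/SNAIL
circuit values of the EMT modeling literature and were then calibrated (see
``analysis/00_calibrate.py`` and docs/methods.md) so that the coupled
circuit is multistable around S = 323-380 thousand molecules and keeps a
hybrid E/M branch over a wider SNAIL window than the core circuit.  They
are calibrated defaults, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .topology import (
    MIRNA,
    NetworkTopology,
    core_emt,
    wildtype_coupled,
)


class ParameterError(ValueError):
    """Raised for invalid kinetic parameter values."""


@dataclass(frozen=True)
class ShiftedHillBlock:
    """Threshold, cooperativity and fold change of one shifted Hill factor."""

    threshold: float  # A0, molecules
    cooperativity: int  # n >= 1
    fold_change: float  # lam; >1 activation, <1 inhibition, ==1 inert

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ParameterError("Hill threshold must be positive")
        if int(self.cooperativity) != self.cooperativity or self.cooperativity < 1:
            raise ParameterError("Hill cooperativity must be a positive integer")
        if not self.fold_change > 0:
            raise ParameterError("Hill fold change must be positive")


@dataclass(frozen=True)
class MicroRnaCoupling:
    """Binding-site model of microRNA action on a target mRNA.

    ``l[i]``, ``gamma_m[i]`` and ``gamma_mu[i]`` give, for ``i`` occupied
    sites, the translation-rate factor, the mRNA active-degradation rate
    (1/h) and the per-duplex microRNA co-degradation rate (1/h).
    """

    mu0: float  # per-site microRNA threshold, molecules
    n_sites: int
    l: tuple[float, ...]
    gamma_m: tuple[float, ...]
    gamma_mu: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ParameterError("mu0 must be positive")
        if self.n_sites < 1:
            raise ParameterError("n_sites must be >= 1")
        for name in ("l", "gamma_m", "gamma_mu"):
            v = getattr(self, name)
            if len(v) != self.n_sites + 1:
                raise ParameterError(f"{name} must have length n_sites+1")
            if any(x < 0 for x in v):
                raise ParameterError(f"{name} entries must be non-negative")
        if self.l[0] != 1.0:
            raise ParameterError("l[0] must be 1 (free mRNA translates at full rate)")
        if self.gamma_m[0] != 0.0 or self.gamma_mu[0] != 0.0:
            raise ParameterError("gamma_m[0] and gamma_mu[0] must be 0")


# Mechanistic dynamical species, in state-vector order.  SNAIL is clamped
# (not a state variable); ZEB is split into mRNA and protein.
CORE_SPECIES = ("mu", "mz", "Z")
COUPLED_SPECIES = ("mu", "mz", "Z", "E", "N")

# Edges carrying a shifted Hill factor in each model, keyed (source, target)
# by topology node names.  The mirna edge miR200->ZEB uses the binding-site
# block instead (or a Hill fallback when mirna_mode == "hill").
CORE_HILL_EDGES = (("SNAIL", "ZEB"), ("SNAIL", "miR200"), ("ZEB", "miR200"),
                   ("ZEB", "ZEB"))
COUPLED_HILL_EDGES = CORE_HILL_EDGES + (
    ("ZEB", "Ecad"), ("Ecad", "ZEB"),
    ("NFATc", "ZEB"), ("NFATc", "miR200"), ("NFATc", "Ecad"),
)


@dataclass
class MechanisticParameters:
    """Full kinetic parameterisation of the mechanistic model.

    ``production``/``degradation`` are keyed by species symbol ("mu",
    "mz", "Z", "E", "N"); ``hill`` is keyed by topology edge (source,
    target).  ``snail`` is the clamped SNAIL input S in molecules.
    """

    production: dict[str, float]
    degradation: dict[str, float]
    hill: dict[tuple[str, str], ShiftedHillBlock]
    mirna: MicroRnaCoupling
    snail: float = 0.0
    mirna_mode: str = "binding_site"  # or "hill", using hill[("miR200","ZEB")]
    species: tuple[str, ...] = COUPLED_SPECIES

    def __post_init__(self) -> None:
        for sp in self.species:
            if sp not in self.production or sp not in self.degradation:
                raise ParameterError(f"missing production/degradation for {sp}")
            if not (self.production[sp] > 0 and self.degradation[sp] > 0):
                raise ParameterError(f"g and k must be positive for {sp}")
        if self.snail < 0:
            raise ParameterError("snail level must be non-negative")
        if self.mirna_mode not in ("binding_site", "hill"):
            raise ParameterError("mirna_mode must be 'binding_site' or 'hill'")

    @property
    def is_coupled(self) -> bool:
        return "N" in self.species

    def with_snail(self, S: float) -> "MechanisticParameters":
        return replace(self, snail=float(S))

    def copy(self) -> "MechanisticParameters":
        return replace(
            self,
            production=dict(self.production),
            degradation=dict(self.degradation),
            hill=dict(self.hill),
        )

    # ------------------------------------------------------------------
    def nfatc_neutralized(self) -> "MechanisticParameters":
        """Coupled parameters with every edge absent from the core circuit
        made inert (fold change 1): the (mu, mz, Z) dynamics then reduce
        exactly to the core model's."""
        p = self.copy()
        for key in p.hill:
            if key not in CORE_HILL_EDGES:
                p.hill[key] = replace(p.hill[key], fold_change=1.0)
        return p

    def to_core(self) -> "MechanisticParameters":
        """Project onto the 3-species core model (drop E, N and their edges)."""
        return MechanisticParameters(
            production={sp: self.production[sp] for sp in CORE_SPECIES},
            degradation={sp: self.degradation[sp] for sp in CORE_SPECIES},
            hill={k: v for k, v in self.hill.items() if k in CORE_HILL_EDGES},
            mirna=self.mirna,
            snail=self.snail,
            mirna_mode=self.mirna_mode,
            species=CORE_SPECIES,
        )

    # ------------------------------------------------------------------
    # flat scalar view, used by sensitivity analysis and the TSV format
    # ------------------------------------------------------------------
    def scalar_names(self) -> list[str]:
        """Continuous scalar parameters (Hill cooperativities and the
        per-site microRNA vectors are excluded by design)."""
        names = [f"g_{sp}" for sp in self.species]
        names += [f"k_{sp}" for sp in self.species]
        for (src, tgt) in sorted(self.hill):
            names.append(f"A0_{src}_{tgt}")
            names.append(f"lam_{src}_{tgt}")
        names.append("mu0")
        return names

    def get_scalar(self, name: str) -> float:
        kind, _, rest = name.partition("_")
        if name == "mu0":
            return self.mirna.mu0
        if kind == "g":
            return self.production[rest]
        if kind == "k":
            return self.degradation[rest]
        src, tgt = rest.split("_")
        block = self.hill[(src, tgt)]
        return block.threshold if kind == "A0" else block.fold_change

    def set_scalar(self, name: str, value: float) -> None:
        kind, _, rest = name.partition("_")
        if name == "mu0":
            self.mirna = replace(self.mirna, mu0=value)
            return
        if kind == "g":
            self.production[rest] = value
            return
        if kind == "k":
            self.degradation[rest] = value
            return
        src, tgt = rest.split("_")
        block = self.hill[(src, tgt)]
        if kind == "A0":
            self.hill[(src, tgt)] = replace(block, threshold=value)
        else:
            self.hill[(src, tgt)] = replace(block, fold_change=value)


# ---------------------------------------------------------------------------
# Default (calibrated) parameter sets
# ---------------------------------------------------------------------------

def _default_mirna() -> MicroRnaCoupling:
    # Six miR-200 sites on ZEB mRNA; silencing factors from the published
    # core-circuit binding-site tables.
    return MicroRnaCoupling(
        mu0=10_000.0,
        n_sites=6,
        l=(1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
        gamma_m=(0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0),
        # microRNA co-degradation calibrated to 0.5x the literature values;
        # weaker duplex-mediated miR-200 loss keeps the partially silenced
        # hybrid branch viable over the SNAIL window used throughout.
        gamma_mu=(0.0, 0.0025, 0.025, 0.25, 0.25, 0.25, 0.25),
    )


def default_core_parameters(snail: float = 0.0) -> MechanisticParameters:
    """Calibrated defaults for the 3-species core EMT circuit."""
    return MechanisticParameters(
        production={"mu": 2100.0, "mz": 11.0, "Z": 100.0},
        degradation={"mu": 0.05, "mz": 0.5, "Z": 0.1},
        hill={
            ("SNAIL", "ZEB"): ShiftedHillBlock(180_000.0, 2, 10.0),
            ("SNAIL", "miR200"): ShiftedHillBlock(180_000.0, 2, 0.1),
            ("ZEB", "miR200"): ShiftedHillBlock(220_000.0, 3, 0.1),
            ("ZEB", "ZEB"): ShiftedHillBlock(25_000.0, 2, 7.5),
        },
        mirna=_default_mirna(),
        snail=snail,
        species=CORE_SPECIES,
    )


def default_coupled_parameters(snail: float = 0.0) -> MechanisticParameters:
    """Calibrated defaults for the 5-species coupled EMT-NFATc circuit.

    NFATc is constitutive, so at steady state N* = g_N/k_N = 1000 molecules
    and each NFATc Hill factor sits at (1+lam)/2 (thresholds at N*).
    """
    p = default_core_parameters(snail)
    hill = dict(p.hill)
    hill.update({
        ("ZEB", "Ecad"): ShiftedHillBlock(220_000.0, 2, 0.1),
        ("Ecad", "ZEB"): ShiftedHillBlock(100_000.0, 2, 0.48),
        ("NFATc", "ZEB"): ShiftedHillBlock(1_000.0, 2, 1.3),
        ("NFATc", "miR200"): ShiftedHillBlock(1_000.0, 2, 1.25),
        ("NFATc", "Ecad"): ShiftedHillBlock(1_000.0, 2, 2.0),
    })
    production = dict(p.production)
    degradation = dict(p.degradation)
    production.update({"E": 10_000.0, "N": 100.0})
    degradation.update({"E": 0.05, "N": 0.1})
    return MechanisticParameters(
        production=production,
        degradation=degradation,
        hill=hill,
        mirna=p.mirna,
        snail=snail,
        species=COUPLED_SPECIES,
    )


def parameters_for(topology: NetworkTopology, snail: float = 0.0
                   ) -> MechanisticParameters:
    """Defaults matching one of the two shipped mechanistic topologies."""
    names = set(topology.nodes)
    if names == set(core_emt().nodes):
        return default_core_parameters(snail)
    if names == set(wildtype_coupled().nodes):
        return default_coupled_parameters(snail)
    raise ParameterError(
        "no shipped mechanistic defaults for this topology; supply a parameter file"
    )


# ---------------------------------------------------------------------------
# TSV round trip (name <tab> value)
# ---------------------------------------------------------------------------

def write_parameters(params: MechanisticParameters, path: str | Path) -> None:
    rows = [("model", "coupled" if params.is_coupled else "core"),
            ("mirna_mode", params.mirna_mode),
            ("snail", repr(params.snail))]
    for name in params.scalar_names():
        rows.append((name, repr(params.get_scalar(name))))
    for (src, tgt), block in sorted(params.hill.items()):
        rows.append((f"n_{src}_{tgt}", str(block.cooperativity)))
    mi = params.mirna
    rows.append(("n_sites", str(mi.n_sites)))
    for vec in ("l", "gamma_m", "gamma_mu"):
        rows.append((vec, ",".join(repr(x) for x in getattr(mi, vec))))
    Path(path).write_text("\n".join(f"{k}\t{v}" for k, v in rows) + "\n")


def read_parameters(path: str | Path) -> MechanisticParameters:
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParameterError(f"{path}: line {lineno}: expected name<TAB>value")
        kv[parts[0]] = parts[1]
    base = (default_coupled_parameters() if kv.get("model") == "coupled"
            else default_core_parameters()).copy()
    base.mirna_mode = kv.get("mirna_mode", "binding_site")
    n_sites = int(kv.get("n_sites", base.mirna.n_sites))
    vecs = {}
    for vec in ("l", "gamma_m", "gamma_mu"):
        vecs[vec] = (tuple(float(x) for x in kv[vec].split(","))
                     if vec in kv else getattr(base.mirna, vec))
    base.mirna = MicroRnaCoupling(mu0=float(kv.get("mu0", base.mirna.mu0)),
                                  n_sites=n_sites, **vecs)
    for (src, tgt) in list(base.hill):
        key = f"n_{src}_{tgt}"
        if key in kv:
            base.hill[(src, tgt)] = replace(base.hill[(src, tgt)],
                                            cooperativity=int(kv[key]))
    for name in base.scalar_names():
        if name in kv and name != "mu0":
            base.set_scalar(name, float(kv[name]))
    base.snail = float(kv.get("snail", 0.0))
    return base
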