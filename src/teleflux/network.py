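"""Mass-action reaction networks with per-gene stochastic turnover attachments.

A :class:`ReactionNetwork` holds an ordered species list, mass-action
reactions, per-species first-order degradation rates and, for "native"
proteins, an attached telegraph turnover model whose synthesis term
(``k_p * mRNA``) feeds the species.  Networks round-trip through a small
YAML dialect (see :func:`network_from_yaml`) in which reactions are written
as ``"A + B -> C @ 1.2e-3"``.

All rates are per hour; bimolecular rate constants are per molecule per hour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import yaml

from teleflux.turnover import (
    GeneExpressionState,
    TurnoverObservables,
    TurnoverParams,
    params_from_observables,
)

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "CellState",
    "Intervention",
    "parse_reaction",
    "network_from_yaml",
    "network_to_yaml",
    "deterministic_counterpart",
]

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_]\w*)\s*$")


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction (reversible ones are two reactions)."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0, got {self.rate}")

    def __str__(self) -> str:
        def side(terms):
            if not terms:
                return "0"
            return " + ".join(f"{n} {s}" if n > 1 else s for s, n in terms)

        return f"{side(self.reactants)} -> {side(self.products)} @ {self.rate:g}"


def _parse_side(text: str) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if text in ("", "0"):
        return ()
    terms = []
    for piece in text.split("+"):
        m = _TERM_RE.match(piece)
        if m is None:
            raise ValueError(f"cannot parse reaction term {piece!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), coef))
    return tuple(terms)


def parse_reaction(text: str) -> Reaction:
    """Parse ``"A + 2 B -> C @ rate"`` into a :class:`Reaction`."""
    if "@" not in text or "->" not in text:
        raise ValueError(f"reaction must look like 'A + B -> C @ rate', got {text!r}")
    body, rate_s = text.rsplit("@", 1)
    lhs, rhs = body.split("->")
    return Reaction(_parse_side(lhs), _parse_side(rhs), float(rate_s))


class ReactionNetwork:
    """Species, mass-action reactions, degradation, and turnover attachments."""

    def __init__(
        self,
        species: list[str],
        reactions: list[Reaction | str],
        degradation: dict[str, float] | None = None,
        turnover: dict[str, TurnoverParams | TurnoverObservables] | None = None,
        initial: dict[str, float] | None = None,
    ) -> None:
        if len(set(species)) != len(species):
            raise ValueError("duplicate species names")
        self.species = list(species)
        self.index = {s: i for i, s in enumerate(self.species)}
        self.reactions = [
            parse_reaction(r) if isinstance(r, str) else r for r in reactions
        ]
        for rxn in self.reactions:
            for s, _ in rxn.reactants + rxn.products:
                if s not in self.index:
                    raise ValueError(f"reaction references undeclared species {s!r}")
        self.degradation = dict(degradation or {})
        for s, d in self.degradation.items():
            if s not in self.index:
                raise ValueError(f"degradation of undeclared species {s!r}")
            if d < 0:
                raise ValueError(f"degradation rate of {s!r} must be >= 0")
        self.turnover: dict[str, TurnoverParams] = {}
        for s, tv in (turnover or {}).items():
            if s not in self.index:
                raise ValueError(f"turnover attached to undeclared species {s!r}")
            if isinstance(tv, TurnoverObservables):
                tv = params_from_observables(tv)
            self.turnover[s] = tv
        self.initial = dict(initial or {})
        for s in self.initial:
            if s not in self.index:
                raise ValueError(f"initial level of undeclared species {s!r}")
        self._compiled: "_CompiledNetwork | None" = None

    # -- structural helpers -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def genes(self) -> list[str]:
        """Names of turnover-attached native species, in species order."""
        return [s for s in self.species if s in self.turnover]

    def degradation_vector(self) -> np.ndarray:
        """Per-species first-order decay rates; attached natives use gamma_p."""
        d = np.zeros(self.n_species)
        for s, rate in self.degradation.items():
            d[self.index[s]] = rate
        for s, tv in self.turnover.items():
            d[self.index[s]] = tv.gamma_p
        return d

    def compiled(self) -> "_CompiledNetwork":
        if self._compiled is None:
            self._compiled = _CompiledNetwork(self)
        return self._compiled

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(
            list(self.species),
            list(self.reactions),
            dict(self.degradation),
            dict(self.turnover),
            dict(self.initial),
        )

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, "
            f"{len(self.reactions)} reactions, {len(self.turnover)} genes)"
        )


class _CompiledNetwork:
    """Padded index/stoichiometry arrays consumed by the numba ODE kernels."""

    MAX_REACTANTS = 3

    def __init__(self, net: ReactionNetwork) -> None:
        nr, ns = len(net.reactions), net.n_species
        self.rates = np.array([r.rate for r in net.reactions], dtype=float)
        self.reactant_idx = np.full((nr, self.MAX_REACTANTS), -1, dtype=np.int64)
        self.reactant_st = np.zeros((nr, self.MAX_REACTANTS), dtype=np.int64)
        net_stoich = np.zeros((nr, ns))
        for j, rxn in enumerate(net.reactions):
            slot = 0
            for s, coef in rxn.reactants:
                if slot >= self.MAX_REACTANTS:
                    raise ValueError("reactions with >3 reactant slots unsupported")
                self.reactant_idx[j, slot] = net.index[s]
                self.reactant_st[j, slot] = coef
                slot += 1
                net_stoich[j, net.index[s]] -= coef
            for s, coef in rxn.products:
                net_stoich[j, net.index[s]] += coef
        # sparse (padded) net-stoichiometry rows
        max_nz = max((int(np.count_nonzero(r)) for r in net_stoich), default=1) or 1
        self.net_idx = np.full((nr, max_nz), -1, dtype=np.int64)
        self.net_coef = np.zeros((nr, max_nz))
        for j in range(nr):
            nz = np.nonzero(net_stoich[j])[0]
            self.net_idx[j, : len(nz)] = nz
            self.net_coef[j, : len(nz)] = net_stoich[j, nz]
        self.deg = net.degradation_vector()
        self.gene_names = net.genes
        self.gene_idx = np.array([net.index[g] for g in self.gene_names], dtype=np.int64)
        self.k_p = np.array([net.turnover[g].k_p for g in self.gene_names])


@dataclass
class CellState:
    """Full state of one cell: clock, per-gene expression states, species vector."""

    time: float
    gene_states: dict[str, GeneExpressionState]
    species_levels: np.ndarray

    def copy(self) -> "CellState":
        return CellState(
            self.time,
            {g: s.copy() for g, s in self.gene_states.items()},
            self.species_levels.copy(),
        )

    def level(self, network: ReactionNetwork, name: str) -> float:
        return float(self.species_levels[network.index[name]])


@dataclass(frozen=True)
class Intervention:
    """A discontinuity applied during simulation.

    ``action`` is one of ``"add_species"`` (add ``amount`` molecules of
    ``species``), ``"block_synthesis"`` (all translation rates k_p set to 0,
    the cycloheximide idealization) or ``"rescale_dose"`` (multiply ``species``
    level by ``factor``).
    """

    time: float
    action: str
    species: str | None = None
    amount: float = 0.0
    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.action not in ("add_species", "block_synthesis", "rescale_dose"):
            raise ValueError(f"unknown intervention action {self.action!r}")
        if self.action in ("add_species", "rescale_dose") and self.species is None:
            raise ValueError(f"{self.action} requires a species name")


def deterministic_counterpart(net: ReactionNetwork) -> ReactionNetwork:
    """The same network with turnover noise removed.

    Every turnover attachment is replaced by constant synthesis at the mean
    rate (a zero-order reaction ``0 -> P @ k_p * <m>``) plus first-order
    degradation at ``gamma_p``, and the species' initial level is set to its
    stationary mean.  A clonal population of this network behaves identically
    cell to cell, which isolates the contribution of gene-expression noise.
    """
    from teleflux.turnover import stationary_moments

    reactions = list(net.reactions)
    degradation = dict(net.degradation)
    initial = dict(net.initial)
    for g, tv in net.turnover.items():
        mom = stationary_moments(tv)
        reactions.append(
            Reaction((), ((g, 1),), tv.k_p * mom.mean_mrna)
        )
        degradation[g] = tv.gamma_p
        initial[g] = mom.mean_protein
    return ReactionNetwork(net.species, reactions, degradation, {}, initial)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

_OBS_KEYS = {
    "mean_protein",
    "mean_mrna",
    "protein_half_life",
    "mrna_half_life",
    "t_on",
    "t_off",
}
_RATE_KEYS = {"k_on", "k_off", "k_m", "gamma_m", "k_p", "gamma_p"}


def _turnover_from_dict(d: dict) -> TurnoverParams:
    keys = set(d)
    if keys <= _RATE_KEYS and keys >= _RATE_KEYS:
        return TurnoverParams(**d)
    if keys == _OBS_KEYS:
        return params_from_observables(TurnoverObservables(**d))
    raise ValueError(
        f"turnover block must give either the six rates {sorted(_RATE_KEYS)} "
        f"or the six observables {sorted(_OBS_KEYS)}, got {sorted(keys)}"
    )


def network_from_dict(doc: dict, rate_scale: float = 1.0) -> ReactionNetwork:
    """Build a network from a config mapping (see the YAML dialect in the docs).

    ``rate_scale`` multiplies every reaction rate constant, so that configs
    stated in per-second units can declare ``time_unit: s`` and be converted
    to the package's per-hour convention.
    """
    scale = rate_scale
    unit = doc.get("time_unit", "h")
    if unit == "s":
        scale *= 3600.0
    elif unit == "min":
        scale *= 60.0
    elif unit != "h":
        raise ValueError(f"unknown time_unit {unit!r}")
    reactions = []
    for r in doc.get("reactions", []):
        rxn = parse_reaction(r) if isinstance(r, str) else r
        reactions.append(Reaction(rxn.reactants, rxn.products, rxn.rate * scale))
    turnover = {
        g: _turnover_from_dict(dict(block))
        for g, block in (doc.get("turnover") or {}).items()
    }
    return ReactionNetwork(
        species=list(doc["species"]),
        reactions=reactions,
        degradation=dict(doc.get("degradation") or {}),
        turnover=turnover,
        initial=dict(doc.get("initial") or {}),
    )


def network_from_yaml(path_or_stream) -> ReactionNetwork:
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(path_or_stream)
    return network_from_dict(doc)


def network_to_yaml(net: ReactionNetwork, path=None) -> str:
    doc = {
        "time_unit": "h",
        "species": list(net.species),
        "reactions": [str(r) for r in net.reactions],
        "degradation": {s: float(v) for s, v in net.degradation.items()},
        "turnover": {
            g: {
                "k_on": tv.k_on,
                "k_off": tv.k_off,
                "k_m": tv.k_m,
                "gamma_m": tv.gamma_m,
                "k_p": tv.k_p,
                "gamma_p": tv.gamma_p,
            }
            for g, tv in net.turnover.items()
        },
        "initial": {s: float(v) for s, v in net.initial.items()},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
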