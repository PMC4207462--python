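"""Deterministic toy networks for tests and demonstrations.

Three miniatures are provided, each exercising one layer of the engine:

* a single-gene network with no reactions (reduces to the pure turnover model);
* a reversible binding network ``A + B <-> C`` (mass conservation when
  synthesis and degradation are switched off);
* a caspase-like activation cascade with a sequestering inhibitor whose
  stochastic expression creates cell-to-cell fate variability (a miniature
  analog of the apoptosis network).
"""

from __future__ import annotations

import os

from teleflux.network import ReactionNetwork, network_to_yaml
from teleflux.turnover import TurnoverObservables

__all__ = [
    "single_gene_network",
    "binding_network",
    "cascade_network",
    "make_fixtures",
]


def single_gene_network(
    mean_protein: float = 1000.0,
    mean_mrna: float = 17.0,
    protein_half_life: float = 27.0,
    mrna_half_life: float = 9.0,
    t_on: float = 0.1,
    t_off: float = 2.6,
) -> ReactionNetwork:
    """One turnover-attached species, no reactions: the engine must reproduce
    the isolated telegraph model exactly."""
    obs = TurnoverObservables(
        mean_protein=mean_protein,
        mean_mrna=mean_mrna,
        protein_half_life=protein_half_life,
        mrna_half_life=mrna_half_life,
        t_on=t_on,
        t_off=t_off,
    )
    return ReactionNetwork(
        species=["P"], reactions=[], turnover={"P": obs}, initial={"P": mean_protein}
    )


def binding_network(
    k_bind: float = 1e-4, k_unbind: float = 0.1, with_turnover: bool = False
) -> ReactionNetwork:
    """Reversible heterodimerization ``A + B <-> C``.

    Without turnover (default) synthesis and degradation are absent, so the
    totals A+C and B+C are conserved along any trajectory.
    """
    turnover = {}
    if with_turnover:
        obs = TurnoverObservables(
            mean_protein=500.0, mean_mrna=10.0, protein_half_life=5.0,
            mrna_half_life=2.0, t_on=0.5, t_off=1.0,
        )
        turnover = {"A": obs, "B": obs}
    return ReactionNetwork(
        species=["A", "B", "C"],
        reactions=[
            f"A + B -> C @ {k_bind}",
            f"C -> A + B @ {k_unbind}",
        ],
        degradation={},
        turnover=turnover,
        initial={"A": 800.0, "B": 500.0, "C": 0.0},
    )


def cascade_network(inhibitor_mean: float = 300.0) -> ReactionNetwork:
    """Miniature signal-to-death cascade with one stochastic inhibitor.

    A ligand L catalytically activates pX -> aX; the inhibitor I sequesters
    aX; aX cleaves the substrate Z -> cZ (the death readout).  pX, I and Z
    carry turnover models; the inhibitor is short-lived with slow promoter
    switching, so its level at treatment time largely decides the outcome —
    raising ``inhibitor_mean`` raises the fraction of surviving cells.
    """
    long_lived = dict(
        mean_mrna=17.0, protein_half_life=27.0, mrna_half_life=9.0,
        t_on=0.1, t_off=2.6,
    )
    return ReactionNetwork(
        species=["L", "pX", "aX", "I", "aX_I", "Z", "cZ"],
        reactions=[
            "L + pX -> L + aX @ 2e-4",
            "aX + I -> aX_I @ 5e-3",
            "aX_I -> aX + I @ 1e-2",
            "aX + Z -> aX + cZ @ 1e-3",
        ],
        degradation={"aX": 0.2, "aX_I": 0.2, "cZ": 0.05},
        turnover={
            "pX": TurnoverObservables(mean_protein=500.0, **long_lived),
            "I": TurnoverObservables(
                mean_protein=inhibitor_mean, mean_mrna=10.0,
                protein_half_life=0.5, mrna_half_life=1.0, t_on=8.0, t_off=12.0,
            ),
            "Z": TurnoverObservables(mean_protein=1000.0, **long_lived),
        },
        initial={"L": 0.0, "pX": 500.0, "I": inhibitor_mean, "Z": 1000.0},
    )


def make_fixtures(outdir: str) -> list[str]:
    """Write the three toy networks as YAML files; idempotent."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, net in (
        ("single_gene.yaml", single_gene_network()),
        ("binding.yaml", binding_network(with_turnover=True)),
        ("cascade.yaml", cascade_network()),
    ):
        path = os.path.join(outdir, name)
        network_to_yaml(net, path)
        written.append(path)
    return written
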