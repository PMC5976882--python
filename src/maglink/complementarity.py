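"""Metabolic complementarity graphs within a culture.

For each metabolite, a directed edge runs from every prototroph (full
biosynthetic pathway) to every auxotroph of the same culture — the
potential donor -> recipient relationships.  A culture with no
prototroph for a metabolite is "omitted" from that metabolite's graph
(nobody can supply it internally), which is exactly the
externally-required case of the community-sufficiency report: the
metabolite must then come from the medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import InvalidParameterError
from .pathways import AuxotrophyProfile


@dataclass
class ComplementarityGraph:
    culture_id: str
    metabolite: str
    #: ordered (donor genome id, recipient genome id) pairs
    edges: set[tuple[str, str]]
    #: True when no member is a prototroph (graph left out of any diagram)
    omitted: bool
    #: genome id -> pathway completeness fraction, carried as node data
    completeness: dict[str, float] = field(default_factory=dict)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(culture=self.culture_id, metabolite=self.metabolite,
                       omitted=self.omitted)
        for gid, c in self.completeness.items():
            g.add_node(gid, completeness=float(c))
        g.add_edges_from(self.edges)
        return g


@dataclass
class SufficiencyReport:
    culture_id: str
    #: metabolite -> "internally-suppliable" | "externally-required"
    status: dict[str, str]

    def externally_required(self) -> set[str]:
        return {m for m, s in self.status.items() if s == "externally-required"}


def build_complementarity(members: list[AuxotrophyProfile], metabolite: str,
                          culture_id: str = "culture") -> ComplementarityGraph:
    """Donor -> recipient edges for one metabolite among one culture's
    members: every prototroph points at every auxotroph."""
    if not members:
        raise InvalidParameterError("member list is empty")
    prototrophs = [m.genome_id for m in members if m.is_prototroph(metabolite)]
    auxotrophs = [m.genome_id for m in members if not m.is_prototroph(metabolite)]
    edges = {(d, r) for d in prototrophs for r in auxotrophs if d != r}
    return ComplementarityGraph(
        culture_id=culture_id, metabolite=metabolite, edges=edges,
        omitted=not prototrophs,
        completeness={m.genome_id: m.completeness.get(metabolite, float("nan"))
                      for m in members})


def community_sufficiency(members: list[AuxotrophyProfile],
                          panel_metabolites: list[str],
                          culture_id: str = "culture") -> SufficiencyReport:
    """A metabolite is internally suppliable iff at least one member
    carries its full pathway; otherwise it must be externally supplied
    (e.g. by the growth medium)."""
    if not members:
        raise InvalidParameterError("member list is empty")
    status = {}
    for metabolite in panel_metabolites:
        any_proto = any(m.is_prototroph(metabolite) for m in members)
        status[metabolite] = "internally-suppliable" if any_proto else "externally-required"
    return SufficiencyReport(culture_id=culture_id, status=status)


def sole_providers(members: list[AuxotrophyProfile],
                   name: str) -> tuple[set[str], bool]:
    """Members able to provide a metabolite (full pathway) or function
    (marker present).  Returns (provider set, is_sole) where is_sole is
    True iff exactly one member provides it."""
    if not members:
        raise InvalidParameterError("member list is empty")
    providers: set[str] = set()
    for m in members:
        if name in m.metabolite_status:
            if m.is_prototroph(name):
                providers.add(m.genome_id)
        elif name in m.function_status:
            if m.has_function(name):
                providers.add(m.genome_id)
        else:
            raise InvalidParameterError(
                f"{name!r} is neither a panel metabolite nor a function marker "
                f"for member {m.genome_id!r}")
    return providers, len(providers) == 1
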