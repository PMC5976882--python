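"""Biosynthetic-pathway completeness and auxotrophy calls.

A pathway is an ordered list of steps; each step is a set of
alternative gene families any one of which performs the step.  A genome
is a prototroph for a metabolite when every step of the metabolite's
pathway is covered by its annotation ("full pathway"), and an auxotroph
otherwise.  Single-gene functions (e.g. catalase-peroxidase) are
modelled as FunctionMarkers: present iff the annotation intersects the
marker's family set.

The shipped default panel covers the seven metabolites relevant to
streamlined freshwater Actinobacteria — pyridoxine, lysine, thiamine,
biotin, riboflavin, vitamin B12 and reduced sulfur (assimilatory
sulfate reduction) — with placeholder gene-family identifiers named
after the canonical bacterial genes.  Real analyses should curate
KO-level definitions; the panel file is plain YAML and editable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import InvalidParameterError, ParseError


@dataclass(frozen=True)
class PathwayDefinition:
    metabolite: str
    #: ordered steps; each step is a tuple of alternative gene families
    steps: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise InvalidParameterError(
                f"pathway {self.metabolite!r} must have at least one step")
        for i, step in enumerate(self.steps):
            if len(step) < 1:
                raise InvalidParameterError(
                    f"pathway {self.metabolite!r} step {i} is empty")


@dataclass(frozen=True)
class FunctionMarker:
    function: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.families:
            raise InvalidParameterError(
                f"marker {self.function!r} has no gene families")


@dataclass
class AuxotrophyProfile:
    """Per-genome prototroph/auxotroph status over a metabolite panel,
    plus presence/absence of single-gene functions."""

    genome_id: str
    #: metabolite -> "prototroph" | "auxotroph"
    metabolite_status: dict[str, str]
    #: function -> "present" | "absent"
    function_status: dict[str, str]
    #: metabolite -> completeness fraction in [0, 1]
    completeness: dict[str, float]

    def is_prototroph(self, metabolite: str) -> bool:
        return self.metabolite_status[metabolite] == "prototroph"

    def has_function(self, function: str) -> bool:
        return self.function_status[function] == "present"


def pathway_completeness(annotation: set[str], definition: PathwayDefinition) -> float:
    """Fraction of pathway steps with at least one alternative family
    present in the annotation."""
    satisfied = sum(1 for step in definition.steps
                    if any(f in annotation for f in step))
    return satisfied / len(definition.steps)


def has_pathway(annotation: set[str], definition: PathwayDefinition,
                completeness_threshold: float = 1.0) -> bool:
    """True iff the pathway is complete.  The default threshold of 1.0
    is the literal "full pathway" rule; a lower threshold tolerates
    annotation noise but is not the default."""
    return pathway_completeness(annotation, definition) >= completeness_threshold


def function_presence(annotation: set[str], marker: FunctionMarker) -> bool:
    """True iff any of the marker's alternative families is annotated."""
    return not annotation.isdisjoint(marker.families)


def auxotrophy_profile(genome_id: str, annotation: set[str],
                       panel: list[PathwayDefinition],
                       markers: list[FunctionMarker] | None = None,
                       completeness_threshold: float = 1.0) -> AuxotrophyProfile:
    """Score one genome against a metabolite panel and function markers."""
    if not panel:
        raise InvalidParameterError("pathway panel is empty")
    names = [p.metabolite for p in panel]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise InvalidParameterError(f"duplicate metabolite in panel: {dup!r}")
    markers = markers or []
    met_status: dict[str, str] = {}
    completeness: dict[str, float] = {}
    for pw in panel:
        c = pathway_completeness(annotation, pw)
        completeness[pw.metabolite] = c
        met_status[pw.metabolite] = ("prototroph"
                                     if c >= completeness_threshold else "auxotroph")
    fun_status = {m.function: ("present" if function_presence(annotation, m)
                               else "absent") for m in markers}
    return AuxotrophyProfile(genome_id=genome_id, metabolite_status=met_status,
                             function_status=fun_status, completeness=completeness)


def load_panel(source) -> tuple[list[PathwayDefinition], list[FunctionMarker]]:
    """Read a pathway panel from YAML (path, file object or string).

    Schema::

        pathways:
          <metabolite>:
            steps:
              - [famA]          # one family
              - [famB, famB2]   # alternatives (OR)
        markers:
          <function>: [famX, famY]
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise ParseError("panel file must contain a 'pathways' mapping")
    panel = []
    for metabolite, body in doc["pathways"].items():
        if not isinstance(body, dict) or "steps" not in body:
            raise ParseError(f"pathway {metabolite!r}: missing 'steps' list")
        steps = tuple(tuple(str(f) for f in step) for step in body["steps"])
        panel.append(PathwayDefinition(metabolite=str(metabolite), steps=steps))
    markers = [FunctionMarker(function=str(name), families=frozenset(str(f) for f in fams))
               for name, fams in (doc.get("markers") or {}).items()]
    return panel, markers


def default_panel() -> list[PathwayDefinition]:
    panel, _ = _load_default()
    return panel


def default_markers() -> list[FunctionMarker]:
    _, markers = _load_default()
    return markers


def _load_default() -> tuple[list[PathwayDefinition], list[FunctionMarker]]:
    with resources.files("maglink.data").joinpath("vitamin_panel.yaml").open() as fh:
        return load_panel(fh)
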