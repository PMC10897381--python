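"""SSN/SOSA-aligned knowledge graph of daily activity observations.

Each labelled participant-day becomes one ``PhysicalActivityObservation``
(a subclass of ``sosa:Observation``) linked to a ``StepsObservation``, a
``SedentaryTimeObservation``, an ``ActivityLevel`` individual (the daily
class 0–4), the observing ``Sensor`` and the person, with the observation
date and the predicted level as literals.  IRIs are minted
deterministically from (person, date) so repeated annotation is idempotent
and merging two day-sets equals annotating their union.

Structural consistency is verified by enumerated checks (domain/range
conformance of the project properties, mandatory cardinalities, and
disjointness of the observation subclasses) rather than a description-logic
reasoner; full OWL reasoning is out of scope for the graph shapes produced
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef, XSD
from rdflib.namespace import OWL, SOSA, SSN

from .mox_io import DayRecord

__all__ = [
    "MOX",
    "ConsistencyVerdict",
    "build_schema",
    "annotate_observations",
    "query_graph",
    "check_consistency",
    "EXAMPLE_QUERIES",
]

log = logging.getLogger(__name__)

#: Project namespace for the activity-observation vocabulary.
MOX = Namespace("https://w3id.org/moxpa/activity#")

_CLASSES = (
    "PhysicalActivityObservation",
    "ActivityLevel",
    "SedentaryTimeObservation",
    "StepsObservation",
    "Sensor",
)
_OBJECT_PROPERTIES = {
    # name: (domain, range)
    "observedActivityLevel": ("PhysicalActivityObservation", "ActivityLevel"),
    "observedSteps": ("PhysicalActivityObservation", "StepsObservation"),
    "observedSedentaryTime": ("PhysicalActivityObservation", "SedentaryTimeObservation"),
}
_DATA_PROPERTIES = ("observationTime", "predictedActivityLevel", "hasPerson")

#: Sibling observation subclasses that must not share an individual.
_DISJOINT_OBSERVATIONS = (
    "PhysicalActivityObservation",
    "StepsObservation",
    "SedentaryTimeObservation",
)


@dataclass
class ConsistencyVerdict:
    violations: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.violations


def _bind(graph: Graph) -> Graph:
    graph.bind("mox", MOX)
    graph.bind("sosa", SOSA)
    graph.bind("ssn", SSN)
    graph.bind("owl", OWL)
    return graph


def build_schema(graph: Graph | None = None) -> Graph:
    """Add the class/property axioms, aligned with the SOSA observation model."""
    g = _bind(graph if graph is not None else Graph())
    for name in _CLASSES:
        g.add((MOX[name], RDF.type, OWL.Class))
    for name in ("PhysicalActivityObservation", "SedentaryTimeObservation", "StepsObservation"):
        g.add((MOX[name], RDFS.subClassOf, SOSA.Observation))
    g.add((MOX.Sensor, RDFS.subClassOf, SOSA.Sensor))
    for name, (dom, rng) in _OBJECT_PROPERTIES.items():
        g.add((MOX[name], RDF.type, OWL.ObjectProperty))
        g.add((MOX[name], RDFS.domain, MOX[dom]))
        g.add((MOX[name], RDFS.range, MOX[rng]))
    g.add((MOX.observedBySensor, RDF.type, OWL.ObjectProperty))
    g.add((MOX.observedBySensor, RDFS.range, MOX.Sensor))
    g.add((MOX.observedBySensor, RDFS.subPropertyOf, SOSA.madeBySensor))
    for name in _DATA_PROPERTIES:
        g.add((MOX[name], RDF.type, OWL.DatatypeProperty))
    for i, a in enumerate(_DISJOINT_OBSERVATIONS):
        for b in _DISJOINT_OBSERVATIONS[i + 1:]:
            g.add((MOX[a], OWL.disjointWith, MOX[b]))
    for code, label in enumerate(("Sedentary", "Low active", "Active", "Medium active", "Highly active")):
        level = MOX[f"level/{code}"]
        g.add((level, RDF.type, MOX.ActivityLevel))
        g.add((level, RDFS.label, Literal(label)))
    return g


def _obs_iri(person: str, date) -> URIRef:
    return MOX[f"observation/{person}/{date.isoformat()}"]


def annotate_observations(
    days: Sequence[DayRecord],
    labels: Sequence[int],
    sensor_id: str = "MOX2-5",
    person_id: str | None = None,
    graph: Graph | None = None,
) -> Graph:
    """One PhysicalActivityObservation per labelled day, SOSA-typed.

    ``person_id`` defaults to each day's participant id.  Days with a
    missing label or date are skipped with a log entry; an empty input
    yields the bare schema graph.
    """
    if not sensor_id:
        raise ValueError("sensor_id must be non-empty")
    if len(labels) != len(days):
        raise ValueError("one label per day required")
    g = build_schema(graph)
    sensor = MOX[f"sensor/{sensor_id}"]
    g.add((sensor, RDF.type, MOX.Sensor))
    for day, label in zip(days, labels):
        if label is None or day.date is None:
            log.warning("skipping day %s/%s: missing label or date",
                        getattr(day, "participant_id", "?"), getattr(day, "date", "?"))
            continue
        person = person_id or day.participant_id
        obs = _obs_iri(person, day.date)
        g.add((obs, RDF.type, MOX.PhysicalActivityObservation))
        g.add((obs, RDF.type, SOSA.Observation))
        g.add((obs, MOX.observedBySensor, sensor))
        g.add((obs, MOX.observationTime, Literal(day.date, datatype=XSD.date)))
        g.add((obs, MOX.hasPerson, Literal(person)))
        g.add((obs, MOX.observedActivityLevel, MOX[f"level/{int(label)}"]))
        g.add((obs, MOX.predictedActivityLevel, Literal(int(label), datatype=XSD.integer)))
        steps_obs = MOX[f"steps/{person}/{day.date.isoformat()}"]
        g.add((steps_obs, RDF.type, MOX.StepsObservation))
        g.add((steps_obs, SOSA.hasSimpleResult, Literal(int(day.steps), datatype=XSD.integer)))
        g.add((obs, MOX.observedSteps, steps_obs))
        sed_obs = MOX[f"sedentary/{person}/{day.date.isoformat()}"]
        g.add((sed_obs, RDF.type, MOX.SedentaryTimeObservation))
        g.add((sed_obs, SOSA.hasSimpleResult, Literal(int(day.sedentary_s), datatype=XSD.integer)))
        g.add((obs, MOX.observedSedentaryTime, sed_obs))
    return g


def query_graph(graph: Graph, query: str) -> list[tuple]:
    """Run a SPARQL query; syntax errors are reported with their position."""
    try:
        result = graph.query(query)
    except Exception as exc:  # pyparsing errors carry location info in str()
        raise ValueError(f"SPARQL syntax error: {exc}") from exc
    return [tuple(row) for row in result]


def check_consistency(graph: Graph) -> ConsistencyVerdict:
    """Structural consistency: domain/range, cardinality and disjointness."""
    v = ConsistencyVerdict()
    typed = {name: set(graph.subjects(RDF.type, MOX[name])) for name in _CLASSES}
    # mandatory cardinalities on physical-activity observations
    for obs in typed["PhysicalActivityObservation"]:
        if not list(graph.objects(obs, MOX.observedBySensor)):
            v.violations.append(f"{obs} lacks an observedBySensor link")
        times = list(graph.objects(obs, MOX.observationTime))
        if len(times) != 1:
            v.violations.append(f"{obs} has {len(times)} observationTime values, expected exactly 1")
    # range and domain conformance of the object properties
    checks = dict(_OBJECT_PROPERTIES)
    checks["observedBySensor"] = (None, "Sensor")
    for prop, (dom, rng) in checks.items():
        for subj, obj in graph.subject_objects(MOX[prop]):
            if dom is not None and subj not in typed[dom]:
                v.violations.append(f"{subj} uses {prop} but is not a {dom}")
            if obj not in typed[rng]:
                v.violations.append(f"{prop} of {subj} targets {obj}, not an individual of {rng}")
    # disjointness of observation subclasses
    for i, a in enumerate(_DISJOINT_OBSERVATIONS):
        for b in _DISJOINT_OBSERVATIONS[i + 1:]:
            for ind in typed[a] & typed[b]:
                v.violations.append(f"{ind} typed as both disjoint classes {a} and {b}")
    return v


#: Supplementary-style retrievals over the observation graph.
EXAMPLE_QUERIES = {
    "count_observations": """
        PREFIX mox: <https://w3id.org/moxpa/activity#>
        SELECT (COUNT(?obs) AS ?n)
        WHERE { ?obs a mox:PhysicalActivityObservation . }
    """,
    "observations_per_person": """
        PREFIX mox: <https://w3id.org/moxpa/activity#>
        SELECT ?person (COUNT(?obs) AS ?n)
        WHERE { ?obs a mox:PhysicalActivityObservation ; mox:hasPerson ?person . }
        GROUP BY ?person ORDER BY ?person
    """,
    "observations_at_level": """
        PREFIX mox: <https://w3id.org/moxpa/activity#>
        SELECT ?obs
        WHERE { ?obs a mox:PhysicalActivityObservation ;
                     mox:predictedActivityLevel ?level .
                FILTER(?level = %(level)d) }
    """,
    "observations_in_window": """
        PREFIX mox: <https://w3id.org/moxpa/activity#>
        PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
        SELECT ?obs ?t
        WHERE { ?obs a mox:PhysicalActivityObservation ; mox:observationTime ?t .
                FILTER(?t >= "%(start)s"^^xsd:date && ?t <= "%(end)s"^^xsd:date) }
        ORDER BY ?t
    """,
}
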