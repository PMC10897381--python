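import datetime as dt

import pytest
from rdflib import Graph, Literal, RDF
from rdflib.namespace import SOSA

from moxpa.mox_io import DayRecord
from moxpa.ontology import (
    EXAMPLE_QUERIES,
    MOX,
    annotate_observations,
    build_schema,
    check_consistency,
    query_graph,
)


def make_days(n, person="P1", start=dt.date(2023, 3, 1), labels=None):
    days = [
        DayRecord(
            participant_id=person, date=start + dt.timedelta(days=i),
            sedentary_s=70_000 + i, lpa_s=4000, mpa_s=1500, vpa_s=300,
            weight_bearing_s=5000, standing_s=6000, steps=8000 + i,
            ima=200_000, minutes_observed=1440,
        )
        for i in range(n)
    ]
    return days, labels if labels is not None else [2] * n


class TestAnnotation:
    def test_one_day_cardinality_contract(self):
        days, labels = make_days(1)
        g = annotate_observations(days, labels)
        assert len(list(g.subjects(RDF.type, MOX.PhysicalActivityObservation))) == 1
        assert len(list(g.subjects(RDF.type, MOX.StepsObservation))) == 1
        assert len(list(g.subjects(RDF.type, MOX.SedentaryTimeObservation))) == 1

    def test_observations_are_sosa_typed(self):
        days, labels = make_days(1)
        g = annotate_observations(days, labels)
        (obs,) = g.subjects(RDF.type, MOX.PhysicalActivityObservation)
        assert (obs, RDF.type, SOSA.Observation) in g

    def test_empty_input_yields_schema_only_graph(self):
        g = annotate_observations([], [])
        assert list(g.subjects(RDF.type, MOX.PhysicalActivityObservation)) == []

    def test_merging_equals_annotating_union(self):
        days, labels = make_days(6)
        whole = annotate_observations(days, labels)
        a = annotate_observations(days[:3], labels[:3])
        b = annotate_observations(days[3:], labels[3:])
        assert set(whole) == set(a) | set(b)

    def test_reannotation_idempotent(self):
        days, labels = make_days(4)
        once = annotate_observations(days, labels)
        twice = annotate_observations(days, labels, graph=annotate_observations(days, labels))
        assert set(once) == set(twice)

    def test_missing_label_skipped_with_log(self, caplog):
        days, _ = make_days(2)
        with caplog.at_level("WARNING"):
            g = annotate_observations(days, [2, None])
        assert len(list(g.subjects(RDF.type, MOX.PhysicalActivityObservation))) == 1
        assert "skipping" in caplog.text


class TestQuerying:
    def test_count_over_ten_days(self):
        days, labels = make_days(10)
        g = annotate_observations(days, labels)
        rows = query_graph(g, EXAMPLE_QUERIES["count_observations"])
        assert int(rows[0][0]) == 10

    def test_select_by_predicted_level(self):
        days, _ = make_days(8)
        labels = [4, 1, 4, 2, 4, 0, 1, 2]
        g = annotate_observations(days, labels)
        rows = query_graph(g, EXAMPLE_QUERIES["observations_at_level"] % {"level": 4})
        assert len(rows) == 3

    def test_person_scoped_query(self):
        days_a, labels_a = make_days(3, person="A")
        days_b, labels_b = make_days(5, person="B")
        g = annotate_observations(days_a + days_b, labels_a + labels_b)
        rows = query_graph(g, EXAMPLE_QUERIES["observations_per_person"])
        assert {str(p): int(n) for p, n in rows} == {"A": 3, "B": 5}

    def test_syntax_error_reported(self):
        g = build_schema()
        with pytest.raises(ValueError, match="SPARQL syntax error"):
            query_graph(g, "SELECT WHERE {")


class TestRoundTripAndConsistency:
    def test_turtle_roundtrip_isomorphic(self, tmp_path):
        days, labels = make_days(5)
        g = annotate_observations(days, labels)
        path = tmp_path / "obs.ttl"
        g.serialize(destination=path, format="turtle")
        g2 = Graph()
        g2.parse(path)
        assert set(g) == set(g2)
        path2 = tmp_path / "obs.owl"
        g.serialize(destination=path2, format="xml")
        g3 = Graph()
        g3.parse(path2)
        assert set(g) == set(g3)

    def test_well_formed_graph_consistent(self):
        days, labels = make_days(5)
        assert check_consistency(annotate_observations(days, labels)).consistent

    def test_missing_observation_time_is_cardinality_violation(self):
        days, labels = make_days(1)
        g = annotate_observations(days, labels)
        (obs,) = g.subjects(RDF.type, MOX.PhysicalActivityObservation)
        g.remove((obs, MOX.observationTime, None))
        verdict = check_consistency(g)
        assert any("observationTime" in v for v in verdict.violations)

    def test_activity_level_pointing_at_sensor_is_range_violation(self):
        days, labels = make_days(1)
        g = annotate_observations(days, labels)
        (obs,) = g.subjects(RDF.type, MOX.PhysicalActivityObservation)
        (sensor,) = g.subjects(RDF.type, MOX.Sensor)
        g.remove((obs, MOX.observedActivityLevel, None))
        g.add((obs, MOX.observedActivityLevel, sensor))
        verdict = check_consistency(g)
        assert any("observedActivityLevel" in v and "ActivityLevel" in v for v in verdict.violations)

    def test_disjoint_double_typing_detected(self):
        days, labels = make_days(1)
        g = annotate_observations(days, labels)
        (obs,) = g.subjects(RDF.type, MOX.PhysicalActivityObservation)
        g.add((obs, RDF.type, MOX.StepsObservation))
        verdict = check_consistency(g)
        assert any("disjoint" in v for v in verdict.violations)
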