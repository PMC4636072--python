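"""Synthetic dataset generator: determinism, bounds, distribution shape."""

import numpy as np
import pytest

from armdb import InMemoryOracle
from armdb.errors import ValidationError
from armdb.fixtures import (
    GENERALIZED_LAB,
    PANEL_ARCHETYPES,
    PERSON_PATIENT,
    REQUEST_IMAGING,
    REQUEST_LAB,
)
from armdb.instance import validate_instance
from armdb.query import Condition, SUBJECT, query
from armdb.synth import (
    PANELS,
    Analyte,
    CountDist,
    DatasetParams,
    generate_dataset,
)

# the thresholds the patient-searching workload applies
THRESHOLDS = {
    "PaO2": (129, 229), "PaCO2": (27,), "Arterial pH": (7.3,), "SaO2": (99,),
    "CaO2": (17,), "Red cell count": (2,), "Alkaline phosphatase": (50,),
    "Thyroid stimulating hormone": (0.3,), "Sodium": (140,),
}


def test_same_seed_yields_byte_identical_streams():
    a = [i.to_json() for i in generate_dataset(DatasetParams(seed=4, n_patients=30))]
    b = [i.to_json() for i in generate_dataset(DatasetParams(seed=4, n_patients=30))]
    assert a == b
    c = [i.to_json() for i in generate_dataset(DatasetParams(seed=5, n_patients=30))]
    assert a != c


def test_every_generated_instance_validates(suite_map):
    for inst in generate_dataset(DatasetParams(seed=2, n_patients=20)):
        validate_instance(inst, suite_map)


def test_infeasible_count_distribution_rejected():
    with pytest.raises(ValidationError, match="min <= mean <= max"):
        CountDist(10, 5, 2)
    with pytest.raises(ValidationError, match="scaling factor"):
        DatasetParams(scale=0)


def test_counts_honor_their_maxima():
    """No patient exceeds the imaging-request maximum over any run."""
    params = DatasetParams(seed=13, n_patients=300)
    per_patient: dict = {}
    per_clinician: dict = {}
    for inst in generate_dataset(params):
        if inst.archetype_id == REQUEST_IMAGING:
            p = inst.values["patient"]["value"]
            per_patient[p] = per_patient.get(p, 0) + 1
        elif inst.archetype_id == PERSON_PATIENT:
            c = inst.values["assignedClinician"]["id"]
            per_clinician[c] = per_clinician.get(c, 0) + 1
    assert max(per_patient.values()) <= params.requests_per_patient.maximum
    assert max(per_clinician.values()) <= params.patients_per_clinician.maximum


def test_empirical_means_track_the_configured_targets():
    """Across 10 seeds at desk scale, per-entity count means stay within
    30% of the generator's own scaled targets."""
    params0 = DatasetParams(seed=0, n_patients=200, scale=0.05)
    targets = {
        "requests": params0.requests_per_patient.mean,
        "images": params0.images_per_exam.scaled(params0.scale).mean,
        "labs": params0.lab_tests_per_patient.scaled(params0.scale).mean,
        "results": params0.results_per_lab_test.scaled(params0.scale).mean,
    }
    sums = {k: [] for k in targets}
    for seed in range(10):
        params = DatasetParams(seed=seed, n_patients=200, scale=0.05)
        n_req = n_img = n_exam = n_lab = n_res = n_gen = 0
        for inst in generate_dataset(params):
            if inst.archetype_id == REQUEST_IMAGING:
                n_req += 1
                for child in inst.values["examItems"]:
                    n_exam += 1
                    n_img += len(child["values"]["imageDetails"])
            elif inst.archetype_id == REQUEST_LAB:
                n_lab += 1
            elif inst.archetype_id == GENERALIZED_LAB:
                n_gen += 1
                n_res += len(inst.values["structureResult"])
        sums["requests"].append(n_req / params.n_patients)
        sums["images"].append(n_img / n_exam)
        sums["labs"].append(n_lab / params.n_patients)
        sums["results"].append(n_res / n_gen)
    for k, target in targets.items():
        mean = float(np.mean(sums[k]))
        assert abs(mean - target) / target < 0.30, (k, mean, target)


def test_analyte_distributions_straddle_the_search_thresholds():
    """Every thresholded analyte puts probability mass on both sides of its
    threshold(s), so searches select nonempty, non-universal sets."""
    rng = np.random.default_rng(99)
    for panel in PANELS:
        for analyte in panel.analytes:
            if analyte.display not in THRESHOLDS:
                continue
            draws = np.array([analyte.draw(rng) for _ in range(2000)])
            for thr in THRESHOLDS[analyte.display]:
                above = float((draws >= thr).mean())
                assert 0.02 < above < 0.98, (analyte.display, thr, above)


def test_pao2_search_selects_strict_nonempty_patient_subset(schema, suite_map):
    """Query 6.1 semantics on the default desk-scale dataset: a nonempty,
    strict subset of all patients."""
    insts = list(generate_dataset(DatasetParams(seed=0)))
    oracle = InMemoryOracle(schema, suite_map)
    oracle.add_all(insts)
    bg = PANEL_ARCHETYPES["blood_gases"]
    hits = oracle.run_query(query(bg, [Condition("paO2", "magnitude", ">=", 129)],
                                  group_unit=SUBJECT))
    n_patients = sum(1 for i in insts if i.archetype_id == PERSON_PATIENT)
    assert 0 < len(hits) < n_patients


def test_cross_panel_search_is_satisfiable_at_desk_scale(schema, suite_map):
    """The five-panel patient search (test 7.2 semantics) returns a nonempty,
    non-universal set under default desk-scale parameters."""
    from armdb.bench import build_queries

    insts = list(generate_dataset(DatasetParams(seed=0)))
    oracle = InMemoryOracle(schema, suite_map)
    oracle.add_all(insts)
    queries = {q.id: q for q in build_queries(None, insts)}
    n_patients = sum(1 for i in insts if i.archetype_id == PERSON_PATIENT)
    for qid in ("6.1", "6.2", "6.3", "7.1", "7.2"):
        rs = oracle.run_query(queries[qid].spec)
        assert 0 < len(rs) < n_patients, (qid, len(rs))
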