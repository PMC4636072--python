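"""Seeded synthetic datasets shaped like the clinical-viewer workload.

The generator emulates the workload's per-entity count distributions --
patients per clinician, imaging requests per patient, images per exam, lab
tests per patient, results per generalized lab test -- each described by a
(minimum, mean, maximum) triple.  Counts are drawn from a log-normal
distribution (sigma = 1) with the stated mean, rounded and truncated to
[min, max]; the heavy right tail matches the large observed maxima.  The
volume-heavy counts (images, lab tests, results) scale by a single factor so
desk-scale datasets keep the workload's shape at a fraction of its size; the
scaled mean of lab tests per patient is floored at the number of panels so
cross-panel patient searches stay meaningful at small scale.

Analyte values are normal around clinical reference midpoints with spreads
wide enough that threshold searches select some, but not all, tested
patients.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import ValidationError
from .fixtures import (
    GENERALIZED_LAB,
    IMAGING_EXAM,
    PANEL_ARCHETYPES,
    PERSON_PATIENT,
    REQUEST_IMAGING,
    REQUEST_LAB,
)
from .instance import ArchetypeInstance


@dataclass(frozen=True)
class CountDist:
    """min/mean/max triple; ``scalable`` counts shrink with the scale factor."""

    minimum: int
    mean: float
    maximum: int
    scalable: bool = False
    #: lower floor for the scaled mean (0 = none)
    mean_floor: float = 0.0

    def __post_init__(self):
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValidationError(
                f"count distribution requires min <= mean <= max, got "
                f"{self.minimum}/{self.mean}/{self.maximum}"
            )

    def scaled(self, scale: float) -> "CountDist":
        if not self.scalable:
            return self
        mean = max(self.minimum, self.mean * scale, self.mean_floor)
        maximum = max(self.minimum, int(round(self.maximum * scale)), int(np.ceil(mean)))
        return CountDist(self.minimum, min(mean, maximum), maximum)

    def draw(self, rng) -> int:
        sigma = 1.0
        mu = np.log(self.mean) - sigma**2 / 2
        x = int(round(float(rng.lognormal(mu, sigma))))
        return int(min(max(x, self.minimum), self.maximum))


@dataclass(frozen=True)
class Analyte:
    node: str
    display: str
    units: str
    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng) -> float:
        v = float(rng.normal(self.mean, self.sd))
        return round(float(min(max(v, self.lo), self.hi)), 2)


@dataclass(frozen=True)
class AnalytePanel:
    name: str
    archetype_id: str
    analytes: tuple


#: Reference-interval midpoints with spreads that put probability mass on
#: both sides of the workload's search thresholds (PaO2 129/229 mmHg, PaCO2
#: 27 mmHg, pH 7.3, SaO2 99 %, CaO2 17 %, RCC 2e12/L, ALP 50 IU/L, TSH 0.3
#: uIU/mL, Na 140 mmol/L).
PANELS = (
    AnalytePanel("blood_gases", PANEL_ARCHETYPES["blood_gases"], (
        Analyte("paO2", "PaO2", "mmHg", 190.0, 55.0, 40.0, 400.0),
        Analyte("paCO2", "PaCO2", "mmHg", 40.0, 10.0, 10.0, 90.0),
        Analyte("arterialPh", "Arterial pH", "pH", 7.40, 0.08, 6.9, 7.8),
        Analyte("saO2", "SaO2", "%", 97.0, 2.5, 70.0, 100.0),
        Analyte("caO2", "CaO2", "%", 18.0, 2.5, 5.0, 30.0),
    )),
    AnalytePanel("full_blood_count", PANEL_ARCHETYPES["full_blood_count"], (
        Analyte("redCellCount", "Red cell count", "10*12/L", 4.6, 1.5, 0.5, 9.0),
        Analyte("whiteCellCount", "White cell count", "10*9/L", 7.0, 2.5, 0.5, 20.0),
        Analyte("haemoglobin", "Haemoglobin", "g/L", 140.0, 20.0, 40.0, 200.0),
    )),
    AnalytePanel("liver_function", PANEL_ARCHETYPES["liver_function"], (
        Analyte("alkalinePhosphatase", "Alkaline phosphatase", "IU/L", 85.0, 35.0, 5.0, 400.0),
        Analyte("alanineAminotransferase", "Alanine aminotransferase", "IU/L",
                30.0, 15.0, 2.0, 300.0),
    )),
    AnalytePanel("thyroid", PANEL_ARCHETYPES["thyroid"], (
        Analyte("thyroidStimulatingHormone", "Thyroid stimulating hormone", "uIU/mL",
                2.0, 1.2, 0.01, 10.0),
        Analyte("freeThyroxine", "Free thyroxine", "pmol/L", 16.0, 4.0, 2.0, 60.0),
    )),
    AnalytePanel("urea_and_electrolytes", PANEL_ARCHETYPES["urea_and_electrolytes"], (
        Analyte("sodium", "Sodium", "mmol/L", 141.0, 4.0, 110.0, 170.0),
        Analyte("potassium", "Potassium", "mmol/L", 4.2, 0.5, 1.5, 9.0),
        Analyte("urea", "Urea", "mmol/L", 5.5, 2.0, 0.5, 40.0),
    )),
)

PANEL_BY_NAME = {p.name: p for p in PANELS}

#: names drawn for repetitions of the generalized lab archetype (distinct
#: from the five panels' analytes so generalized data stays organic)
GENERIC_ANALYTES = (
    ("Glucose", "mmol/L"), ("Calcium", "mmol/L"), ("Phosphate", "mmol/L"),
    ("Magnesium", "mmol/L"), ("Albumin", "g/L"), ("Total protein", "g/L"),
    ("Bilirubin", "umol/L"), ("Creatinine", "umol/L"), ("Uric acid", "umol/L"),
    ("Cholesterol", "mmol/L"), ("Triglycerides", "mmol/L"), ("Amylase", "IU/L"),
    ("Lipase", "IU/L"), ("Lactate", "mmol/L"), ("CRP", "mg/L"),
    ("Ferritin", "ug/L"), ("Iron", "umol/L"), ("Vitamin D", "nmol/L"),
    ("Folate", "nmol/L"), ("B12", "pmol/L"),
)


@dataclass
class DatasetParams:
    seed: int = 0
    n_patients: int = 200
    #: 0 derives one clinician per 7 patients (the workload's mean load)
    n_clinicians: int = 0
    scale: float = 0.05
    patients_per_clinician: CountDist = field(
        default_factory=lambda: CountDist(1, 7, 50))
    requests_per_patient: CountDist = field(
        default_factory=lambda: CountDist(1, 3, 26))
    images_per_exam: CountDist = field(
        default_factory=lambda: CountDist(1, 363, 10664, scalable=True))
    lab_tests_per_patient: CountDist = field(
        default_factory=lambda: CountDist(1, 23, 425, scalable=True,
                                          mean_floor=float(len(PANELS) + 1)))
    results_per_lab_test: CountDist = field(
        default_factory=lambda: CountDist(1, 168, 4477, scalable=True))
    #: weight of the generalized archetype in the panel mix; the five
    #: specialized panels share the remainder equally
    general_weight: float = 0.3
    date_range: tuple = ("2014-01-01", "2014-12-31")

    def __post_init__(self):
        if self.scale <= 0:
            raise ValidationError("scaling factor must be > 0")
        if self.n_clinicians == 0:
            self.n_clinicians = max(1, int(round(self.n_patients / 7)))


def _dt(rng, params) -> str:
    y0 = np.datetime64(params.date_range[0])
    y1 = np.datetime64(params.date_range[1])
    days = int((y1 - y0) / np.timedelta64(1, "D"))
    d = y0 + np.timedelta64(int(rng.integers(0, days + 1)), "D")
    return (
        f"{d}T{int(rng.integers(0, 24)):02d}:"
        f"{int(rng.integers(0, 60)):02d}:{int(rng.integers(0, 60)):02d}"
    )


def _leaf(**fields):
    return dict(fields)


def _assign_clinicians(params, rng) -> list:
    """Patient -> clinician assignment honoring the 1/7/50 load triple."""
    cap = params.patients_per_clinician.maximum
    weights = np.array([params.patients_per_clinician.draw(rng)
                        for _ in range(params.n_clinicians)], dtype=float)
    loads = [0] * params.n_clinicians
    out = []
    for _ in range(params.n_patients):
        w = np.where(np.array(loads) < cap, weights, 0.0)
        if w.sum() == 0:
            w = np.where(np.array(loads) < cap, 1.0, 0.0)
            if w.sum() == 0:  # every clinician full: relax the cap
                w = np.ones(params.n_clinicians)
        c = int(rng.choice(params.n_clinicians, p=w / w.sum()))
        loads[c] += 1
        out.append(c)
    return out


def generate_dataset(params: Optional[DatasetParams] = None) -> Iterator[ArchetypeInstance]:
    """Yield the dataset's instances in a deterministic stream.

    Order: all patients, then per patient the imaging requests (exams nested
    as slot children), then the lab requests with their observations.
    """
    params = params or DatasetParams()
    rng = np.random.default_rng(params.seed)
    images_d = params.images_per_exam.scaled(params.scale)
    labs_d = params.lab_tests_per_patient.scaled(params.scale)
    results_d = params.results_per_lab_test.scaled(params.scale)

    clinician_of = _assign_clinicians(params, rng)
    patients = [f"P{i + 1:05d}" for i in range(params.n_patients)]

    for i, pid in enumerate(patients):
        yield ArchetypeInstance(PERSON_PATIENT, {
            "patientIdentifier": {"identifier": _leaf(id=pid)},
            "personName": {"name": _leaf(value=f"Patient {pid}")},
            "personDetails": {
                "sex": _leaf(definingCode_code=("M" if rng.random() < 0.5 else "F")),
            },
            "assignedClinician": _leaf(id=f"C{clinician_of[i] + 1:03d}"),
        })

    req_no = exam_no = lab_no = 0
    n_panels = len(PANELS)
    panel_names = [p.name for p in PANELS]
    pw = (1.0 - params.general_weight) / n_panels
    mix = np.array([pw] * n_panels + [params.general_weight])

    for pid in patients:
        # imaging: requests with one exam each (the request/exam slot)
        n_req = params.requests_per_patient.draw(rng)
        for _ in range(n_req):
            req_no += 1
            exam_no += 1
            rid = f"IRQ{req_no:07d}"
            eid = f"IEX{exam_no:07d}"
            n_img = images_d.draw(rng)
            exam = {
                "archetype_id": IMAGING_EXAM,
                "values": {
                    "id": _leaf(id=eid),
                    "receiverOrderIdentifier": _leaf(id=rid),
                    "patient": _leaf(value=pid),
                    "examDateTime": _leaf(value=_dt(rng, params)),
                    "imageDetails": [
                        {
                            "image": _leaf(uri_value=f"pacs://{eid}/{k + 1}"),
                            "imageNumber": _leaf(magnitude=k + 1),
                        }
                        for k in range(n_img)
                    ],
                },
            }
            yield ArchetypeInstance(REQUEST_IMAGING, {
                "id": _leaf(id=rid),
                "requestorIdentifier": _leaf(value=f"C{int(rng.integers(params.n_clinicians)) + 1:03d}"),
                "receiverIdentifier": _leaf(value=f"RIS{req_no:07d}"),
                "patient": _leaf(value=pid),
                "requestDateTime": _leaf(value=_dt(rng, params)),
                "examName": _leaf(value=f"Exam {int(rng.integers(1, 40))}"),
                "examItems": [exam],
            })

        # laboratory: one request per test; panels cycle in a random order so
        # a patient's first tests cover distinct panels, then follow the mix
        n_lab = labs_d.draw(rng)
        order = list(rng.permutation(panel_names + ["general"]))
        for t in range(n_lab):
            lab_no += 1
            lrid = f"LRQ{lab_no:07d}"
            if t < len(order):
                kind = order[t]
            else:
                kind = (panel_names + ["general"])[int(rng.choice(n_panels + 1, p=mix))]
            yield ArchetypeInstance(REQUEST_LAB, {
                "receiverIdentifier": _leaf(value=lrid),
                "requestorIdentifier": _leaf(value=f"C{int(rng.integers(params.n_clinicians)) + 1:03d}"),
                "patient": _leaf(value=pid),
                "requestDateTime": _leaf(value=_dt(rng, params)),
            })
            if kind == "general":
                n_res = results_d.draw(rng)
                picks = rng.integers(0, len(GENERIC_ANALYTES), size=n_res)
                yield ArchetypeInstance(GENERALIZED_LAB, {
                    "id": _leaf(id=f"LAB{lab_no:07d}"),
                    "receiverOrderIdentifier": _leaf(value=lrid),
                    "patient": _leaf(value=pid),
                    "testDateTime": _leaf(value=_dt(rng, params)),
                    "structureResult": [
                        {
                            "testItem": _leaf(value=GENERIC_ANALYTES[int(k)][0]),
                            "result": _leaf(value=f"{float(rng.normal(50, 20)):.2f}"),
                            "resultUnit": _leaf(value=GENERIC_ANALYTES[int(k)][1]),
                        }
                        for k in picks
                    ],
                })
            else:
                panel = PANEL_BY_NAME[kind]
                values = {
                    "receiverOrderIdentifier": _leaf(value=lrid),
                    "patient": _leaf(value=pid),
                    "testDateTime": _leaf(value=_dt(rng, params)),
                }
                for a in panel.analytes:
                    values[a.node] = _leaf(magnitude=a.draw(rng), units=a.units)
                yield ArchetypeInstance(panel.archetype_id, values)


def generate_dataset_list(params: Optional[DatasetParams] = None) -> list:
    return list(generate_dataset(params))


def write_jsonl(instances, path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as f:
        for inst in instances:
            f.write(inst.to_json() + "\n")
            n += 1
    return n


def read_jsonl(path) -> Iterator[ArchetypeInstance]:
    with open(path, encoding="utf-8") as f:
        for line in f:
            line = line.strip()
            if line:
                yield ArchetypeInstance.from_json(line)
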