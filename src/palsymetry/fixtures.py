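"""Packaged reference cohort and the one-call reproduction pipeline.

``data/table1.csv`` holds the published per-subject index values of the
38-subject study cohort — 20 healthy volunteers, 10 mild and 8 severe
central-facial-palsy patients, each with their SMM and DMS printed to two
decimals — so the statistical comparison and classification stages can be
re-run end to end without any video data.  The file is checksum-guarded
against accidental edits: these numbers are transcribed reference values,
not computed ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .classify import CvPrediction, RocReport, evaluate_records
from .cohort import GroupTestResult, SubjectRecord, compare_groups
from .errors import FixtureIntegrityError

__all__ = ["load_table1", "run_reproduction", "ReproductionReport"]

_TABLE1_SHA256 = "a93e037c48f22772f24e0482679db810e9e8e877b7e6ea2410ebce4dbe864467"


def load_table1() -> list[SubjectRecord]:
    """The 38-subject reference cohort (20 healthy, 10 mild, 8 severe)."""
    path = resources.files("palsymetry").joinpath("data/table1.csv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureIntegrityError(
            f"table1.csv checksum mismatch ({digest}); the packaged cohort was modified"
        )
    df = pd.read_csv(path)
    return [
        SubjectRecord(r.subject_id, r.group, float(r.smm), float(r.dms))
        for r in df.itertuples()
    ]


@dataclass(frozen=True)
class ReproductionReport:
    smm_test: GroupTestResult
    dms_test: GroupTestResult
    predictions: list[CvPrediction]
    roc: RocReport

    def to_dict(self) -> dict:
        tp, fn, fp, tn = self.roc.confusion
        return {
            "n_subjects": len(self.predictions),
            "mann_whitney": {
                "smm": {"U": self.smm_test.u_statistic, "p": self.smm_test.p_value,
                        "method": self.smm_test.method},
                "dms": {"U": self.dms_test.u_statistic, "p": self.dms_test.p_value,
                        "method": self.dms_test.method},
            },
            "auc": self.roc.auc,
            "youden_cutoff": self.roc.youden_cutoff,
            "sensitivity": self.roc.sensitivity,
            "specificity": self.roc.specificity,
            "accuracy": self.roc.accuracy,
            "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
            "loocv_probabilities": {
                p.subject_id: p.probability for p in self.predictions
            },
        }


def run_reproduction(records: list[SubjectRecord] | None = None) -> ReproductionReport:
    """Run the full statistics + classification pipeline on the reference
    cohort (or any record list).  Fully deterministic."""
    if records is None:
        records = load_table1()
    smm_test, dms_test = compare_groups(records)
    preds, roc = evaluate_records(records)
    return ReproductionReport(
        smm_test=smm_test, dms_test=dms_test, predictions=preds, roc=roc
    )
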