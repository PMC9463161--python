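"""Per-visit scoring, ON/OFF discrimination and agreement with the clinician.

Per-walk predictions are averaged into one score per visit.  For every
subject with at least one ON and one OFF visit the ON-visit and OFF-visit
means (mu_ON, mu_OFF) are compared: the medication cycle is considered
correctly resolved when mu_OFF > mu_ON, since symptoms are worse with the
drug worn off.  Agreement with the clinician is the coefficient of
determination between the per-state means and the corresponding clinician
PIGD means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import Discriminator
from .preprocess import ExampleSet
from .simulate import MedState
from .train import predict_scores

log = logging.getLogger(__name__)

PROTOCOLS = ("paired_two_visit", "multi_visit_on_off")


@dataclass
class EvaluationReport:
    """ON/OFF accuracy and R^2 of predictions against clinician scores."""

    on_off_accuracy: float
    clinician_on_off_accuracy: float
    r_squared: float
    n_subjects_counted: int
    protocol: str
    per_subject: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "on_off_accuracy": self.on_off_accuracy,
            "clinician_on_off_accuracy": self.clinician_on_off_accuracy,
            "r_squared": self.r_squared,
            "n_subjects_counted": self.n_subjects_counted,
            "per_subject": self.per_subject.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def score_visits(disc: Discriminator, examples: ExampleSet) -> pd.DataFrame:
    """Average the score head over every walk of each visit (inference mode).

    Returns one row per visit: subject_id, visit_id, state, mean_pred,
    clinician_score, n_walks.
    """
    if len(examples) == 0:
        return pd.DataFrame(columns=["subject_id", "visit_id", "state",
                                     "mean_pred", "clinician_score", "n_walks"])
    preds = predict_scores(disc, examples)
    df = examples.meta.copy()
    df["pred"] = preds
    rows = (df.groupby(["subject_id", "visit_id"], sort=True)
              .agg(state=("state", "first"),
                   mean_pred=("pred", "mean"),
                   clinician_score=("pigd_score", "first"),
                   n_walks=("pred", "size"))
              .reset_index())
    return rows


def aggregate_on_off(visit_scores: pd.DataFrame,
                     protocol: str = "multi_visit_on_off") -> pd.DataFrame:
    """Collapse visit scores into per-subject (mu_ON, mu_OFF) rows.

    TRANSITIONING visits are dropped; under ``paired_two_visit`` a subject
    must have exactly one ON and one OFF visit, under ``multi_visit_on_off``
    at least one of each (others are excluded and logged).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    vs = visit_scores[visit_scores["state"].isin([MedState.ON.value,
                                                  MedState.OFF.value])]
    rows = []
    for sid, grp in vs.groupby("subject_id", sort=True):
        on = grp[grp["state"] == MedState.ON.value]
        off = grp[grp["state"] == MedState.OFF.value]
        if protocol == "paired_two_visit" and (len(on) != 1 or len(off) != 1):
            log.info("subject %s excluded: paired protocol needs exactly one "
                     "ON and one OFF visit (has %d/%d)", sid, len(on), len(off))
            continue
        if len(on) == 0 or len(off) == 0:
            log.debug("subject %s excluded: missing an ON or OFF visit", sid)
            continue
        rows.append({
            "subject_id": sid,
            "mu_on": float(on["mean_pred"].mean()),
            "mu_off": float(off["mean_pred"].mean()),
            "mu_hat_on": float(on["clinician_score"].mean()),
            "mu_hat_off": float(off["clinician_score"].mean()),
        })
    return pd.DataFrame(rows, columns=["subject_id", "mu_on", "mu_off",
                                       "mu_hat_on", "mu_hat_off"])


def on_off_accuracy(subject_rows: pd.DataFrame, use_predictions: bool = True) -> float:
    """Fraction of counted subjects whose OFF mean strictly exceeds the ON mean.

    Ties count as incorrect.  With ``use_predictions`` False the clinician
    means are compared instead.
    """
    if len(subject_rows) == 0:
        raise ValueError("on_off_accuracy is undefined for zero counted subjects")
    if use_predictions:
        correct = subject_rows["mu_off"].to_numpy() > subject_rows["mu_on"].to_numpy()
    else:
        correct = (subject_rows["mu_hat_off"].to_numpy()
                   > subject_rows["mu_hat_on"].to_numpy())
    return float(np.count_nonzero(correct) / len(subject_rows))


def r_squared(pred, truth, method: str = "determination") -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (default) or squared
    Pearson correlation; the former penalizes miscalibrated predictors and
    can be negative."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("pred and truth must be equal-length with >= 2 entries")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared is undefined for constant truth")
    if method == "determination":
        return 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot
    if method == "pearson":
        return float(np.corrcoef(pred, truth)[0, 1] ** 2)
    raise ValueError("method must be 'determination' or 'pearson'")


def build_report(visit_scores: pd.DataFrame,
                 protocol: str = "multi_visit_on_off",
                 r2_method: str = "determination") -> EvaluationReport:
    """Full evaluation: per-subject ON/OFF aggregation, accuracy, and R^2
    computed from the stacked per-state means (one mu_ON and one mu_OFF per
    counted subject against the clinician's)."""
    rows = aggregate_on_off(visit_scores, protocol)
    if len(rows) == 0:
        raise ValueError("no subjects with both ON and OFF visits to evaluate")
    acc = on_off_accuracy(rows, use_predictions=True)
    clin_acc = on_off_accuracy(rows, use_predictions=False)
    pred = np.concatenate([rows["mu_on"].to_numpy(), rows["mu_off"].to_numpy()])
    truth = np.concatenate([rows["mu_hat_on"].to_numpy(),
                            rows["mu_hat_off"].to_numpy()])
    r2 = r_squared(pred, truth, r2_method)
    return EvaluationReport(on_off_accuracy=acc, clinician_on_off_accuracy=clin_acc,
                            r_squared=r2, n_subjects_counted=len(rows),
                            protocol=protocol, per_subject=rows)
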