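"""Uncorrected two-stage estimation of the biomarker-event association.

Stage 1 fits the linear mixed model to the observed longitudinal data;
stage 2 plugs the subject-specific BLUP predictions, evaluated at every
distinct event time while a subject is at risk, into a time-varying Cox
regression.  Predictions are extrapolated beyond a subject's last
measurement where the risk set requires it, which is the main practical
advantage over carrying raw observations forward.  The plug-in is "naive":
stage-2 standard errors ignore the uncertainty of the stage-1 fit, which is
known to understate them.
"""

from __future__ import annotations

from dataclasses import dataclass

from jmsim import lmm, tvcox
from jmsim.synthetic_data import SimulatedDataset, TrajectorySpec

__all__ = ["TwoStageResult", "run_two_stage"]


@dataclass
class TwoStageResult:
    stage1: lmm.LmmFit
    stage2: tvcox.CoxFit | None
    converged: bool

    def to_dict(self) -> dict:
        return {
            "stage1": self.stage1.to_dict(),
            "stage2": None if self.stage2 is None else self.stage2.to_dict(),
            "converged": bool(self.converged),
        }


def run_two_stage(
    dataset: SimulatedDataset,
    trajectory: TrajectorySpec | None = None,
    method: str = "ml",
    ties: str = "breslow",
) -> TwoStageResult:
    """Run both stages on a dataset (or CSV pair loaded into one).

    Stage-1 non-convergence aborts the pipeline with ``converged=False`` and
    no stage-2 fit, since the survival model cannot be estimated without
    longitudinal predictions.
    """
    if trajectory is None and dataset.config is not None:
        trajectory = dataset.config.trajectory
    fit1 = lmm.fit_lmm(
        dataset.longitudinal, dataset.survival, trajectory=trajectory,
        method=method,
    )
    if not fit1.converged:
        return TwoStageResult(stage1=fit1, stage2=None, converged=False)

    predict = lambda sid, t: lmm.predict_blup(fit1, sid, t)
    cp = tvcox.build_counting_process(
        dataset.longitudinal,
        dataset.survival,
        covariate_source="supplied_function",
        predict_fn=predict,
    )
    fit2 = tvcox.fit_tvcox(cp, ties=ties)
    return TwoStageResult(
        stage1=fit1, stage2=fit2, converged=bool(fit1.converged and fit2.converged)
    )
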