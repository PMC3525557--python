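#!/usr/bin/env python
"""Generate the synthetic two-group treadmill study.

Emulates the treadmill study design — 2 age groups x 16 participants x
3 relative speeds (80/100/120% of preferred) x 2 trials, with 20 step
postures per foot and trial — and writes the step-posture ensembles,
manifest and generative ground truth to scratch/study/.

The older group is generated with a reduced step-length (stepX) null-space
gain (0.2 vs 1.0), inflated baseline angle SDs, and no fore-aft bCoM-fCoM
coupling, mirroring weaker motor-equivalent stabilization of step length.
"""

from pathlib import Path

from gaitcov.model import KinematicModel
from gaitcov.synthetic import StudySpec, generate_study

OUT = Path(__file__).resolve().parents[1] / "scratch" / "study"
SEED = 2026


def main() -> None:
    model = KinematicModel.default()
    study = StudySpec(model=model, seed=SEED)
    result = generate_study(study, out_dir=OUT, overwrite=True)
    print(f"design: {len(study.groups)} groups x {study.n_participants} "
          f"participants x {len(study.speeds)} speeds x {study.n_trials} trials")
    print(f"wrote {study.n_trial_recordings} trial recordings "
          f"({len(result.ensembles)} step-posture ensembles) to {OUT}")
    gt = next(iter(result.ground_truth.values()))
    print("example generative COV (first ensemble):",
          {k: round(v, 2) for k, v in gt["cov_true"].items()})


if __name__ == "__main__":
    main()
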