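"""Run the full cohort pipeline end to end and print the report.

Simulate -> align -> detect -> similarity gate -> epoch -> statistics,
with every intermediate written to the run directory.  This miniature
cohort bypasses detector training (ground-truth events) to stay fast;
set ``do_detect=True`` for the full path.
"""

from tapflow import pipeline

cfg = pipeline.RunConfig(
    out_dir="scratch/example_run",
    seed=4,
    n_subjects=3,
    do_detect=False,
    do_tfr_stats=False,
    do_tactile=False,
    session=dict(duration_s=330.0, n_goal=80, n_nongoal=55,
                 eeg=dict(n_channels=16, eeg_srate=250.0)),
    n_boot=200,
)
run_dir = pipeline.run_all(cfg)
print(pipeline.summarize(run_dir))
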