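"""Write a dataset to disk, then analyze it with the file-based pipeline.

Equivalent to `emdassist pipeline --out <dir>` from a shell.  Uses a
shortened trial length and a reduced EMG rate so the example finishes in
seconds; the on-disk layout (session.csv + per-trial CSVs) is identical
to a full-size run.
"""

import tempfile
from pathlib import Path

from emdassist import GeneratorParams, RunConfig
from emdassist.datasets import run_pipeline

config = RunConfig(
    generator=GeneratorParams(
        n_participants=2, seed=30, emg_rate=500.0, post_cue_s=1.6, pre_cue_rest_s=0.8
    )
)
out = Path(tempfile.mkdtemp(prefix="emdassist_"))
result = run_pipeline(config, out)
print(f"dataset + analysis under {out}")
print((result["out_dir"] / "report.txt").read_text())
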