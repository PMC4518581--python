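"""Run every stage end-to-end and write all reports to disk.

Equivalent to ``promkit run-all --seed 7 --out-dir pipeline_run``: simulate
-> reduce -> scale -> Rasch -> score -> validate, with a JSON manifest
recording the seed and configuration hash for reproducibility.
"""

import tempfile
from pathlib import Path

from promkit.pipeline import run_all

out_dir = Path(tempfile.mkdtemp()) / "pipeline_run"
manifest = run_all(out_dir, seed=7)

print(f"wrote {len(manifest.outputs)} outputs to {out_dir}:")
for stage, fname in manifest.outputs.items():
    print(f"  {stage:>20}: {fname}")
print()
print("Re-running with the same seed reproduces every report byte-for-byte "
      "(the manifest's timestamps aside).")
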