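"""Run the whole simulate -> preprocess -> ia -> analyze chain in one call.

Equivalent to `wordia run --config pipeline.yaml`; produces all on-disk
artifacts plus a hash manifest proving the run is reproducible.
"""

import tempfile
from pathlib import Path

from wordia import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        out_dir=str(Path(tmp) / "out"),
        seed=5,
        simulation={"n_images": 20, "trials_per_participant": 10, "vocab_size": 400},
    )
    manifest = run_pipeline(cfg)
    print("artifacts written:")
    for name, info in manifest.items():
        print(f"  {name:<12} sha256 {info['sha256'][:12]}…")
    print("\n--- report.md ---")
    print(Path(cfg.out_dir, "report.md").read_text())
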