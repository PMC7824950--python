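"""Run the whole analysis as one reproducible report bundle.

Writes a synthetic survey to CSV, then runs validation, descriptive
summaries, consensus indices, community similarity and group statistics in
one pass, emitting CSV tables plus a plain-text summary stamped with the
config hash and seed.
"""

import tempfile
from pathlib import Path

from ethnosurvey import PipelineConfig, SyntheticConfig, generate_survey, run_pipeline, write_survey

workdir = Path(tempfile.mkdtemp(prefix="ethnosurvey_"))
ds, _ = generate_survey(SyntheticConfig(seed=42))
paths = write_survey(ds, workdir / "survey")

cfg = PipelineConfig(
    reports=str(paths["reports"]),
    informants=str(paths["informants"]),
    species=str(paths["species"]),
    out_dir=str(workdir / "report"),
    seed=42,
    pools={"mbanza_ngungu": ["mbanza_ngungu_urban", "mbanza_ngungu_rural"]},
)
outputs = run_pipeline(cfg)

print(f"wrote {len(outputs)} outputs to {cfg.out_dir}:")
for name in sorted(outputs):
    print("  ", name)
print("\nFirst lines of the summary document:")
print("\n".join(Path(outputs["summary.txt"]).read_text().splitlines()[:6]))
print("\nThe same config and seed always reproduce these files byte-for-byte.")
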