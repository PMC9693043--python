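"""Run the full pipeline from a single config: simulate -> report.

Writes the binned matrix, per-comparison model summaries, the masked
screening report, volcano datasets, enrichment results and a manifest
under out_dir; identical config + seed reproduces identical outputs.
"""

import tempfile
from pathlib import Path

import yaml

from gestox import pipeline

with tempfile.TemporaryDirectory() as tmp:
    config_path = Path(tmp) / "run.yaml"
    config_path.write_text(yaml.safe_dump({
        "fluid": "plasma",
        "mode": "synthetic",
        "seed": 42,
        "out_dir": str(Path(tmp) / "run"),
        "simulate": {"n_per_cell": 8, "points": 4096,
                     "effects": [{"metabolite": "Citrate", "day": "D20",
                                  "fold_change": 0.4}]},
        "model": {"n_perm": 50},
    }))
    config = pipeline.validate_config(config_path)
    manifest = pipeline.run(config)

    print(f"status: {manifest.status}; config hash {manifest.config_hash}")
    print(f"significant metabolites: {manifest.counts['significant_names']}")
    print("per-comparison model summaries:")
    for label in sorted(k for k in manifest.models if k.startswith("C")):
        s = manifest.models[label]
        print(f"  {label}: R2Y={s['r2y']:.2f} Q2={s['q2']:+.2f} "
              f"perm p(Q2)={s['permutation_p_q2']:.3f} "
              f"CV-ANOVA p={s['cv_anova_p']:.2e}")
    print("the planted 0.4-fold citrate drop drives the C20-H20 model; flags on "
          "other days are screen false positives at the default, uncorrected rules")
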