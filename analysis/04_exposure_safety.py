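#!/usr/bin/env python
"""Quasi-static induced-field exposure bounds per tissue.

Finding: with B = 8.5621 mT at 100 kHz, the circular-path bound at the
tumor disk radius (12 mm) is ~32 V/m — the same order as the in-tissue
range (33.5–63.1 V/m) of the full anatomical eddy-current problem, which
this estimator deliberately does not solve.  Current densities follow
J = σE with the tabulated conductivities; the near-insulating scalp
(σ = 4.51×10⁻⁴ S/m) carries ~3 orders of magnitude less current than
muscle at the same field.
"""

from pathlib import Path

from mihsim.induced import EXPOSURE_REPORT_NOTE, exposure_report
from mihsim.phantom import TissueRegistry, build_head_phantom

OUT = Path("results")
OUT.mkdir(exist_ok=True)

registry = TissueRegistry.from_csv()
phantom = build_head_phantom()
table = exposure_report(phantom, registry, 8.5621e-3, 1.0e5)

print(EXPOSURE_REPORT_NOTE)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
with open(OUT / "exposure.csv", "w") as f:
    f.write(f"# {EXPOSURE_REPORT_NOTE}\n")
    table.to_csv(f, index=False)
print(f"wrote {OUT/'exposure.csv'}")
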