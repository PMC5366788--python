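"""Consistency-check an atlas, then break it on purpose.

Validates a pristine synthetic atlas (expecting zero findings), injects
a dangling reference and a label-coverage defect into copies, and prints
the findings the validator raises for each mutant.
"""

import tempfile
from pathlib import Path

from atlaskit import generate_fixture_atlas, mutate_atlas, parse_atlas, validate
from atlaskit.validator import findings_to_text

base = Path(tempfile.mkdtemp())
pristine = base / "atlas"
generate_fixture_atlas(pristine, seed=3)

graph = parse_atlas((pristine / "atlas.json").read_text(), strict=False)
findings = validate(graph, data_root=pristine, check_data=True)
print(f"pristine atlas: {len(findings)} findings")

for defect in ("DANGLING_REF", "LABEL_UNUSED"):
    mutant = mutate_atlas(pristine, defect, dest_dir=base / defect.lower())
    g = parse_atlas((mutant / "atlas.json").read_text(), strict=False)
    found = validate(g, data_root=mutant, check_data=True)
    print(f"\nafter injecting {defect}:")
    print(findings_to_text(found), end="")

# A clean atlas reports nothing; each mutant reports exactly the injected
# rule, with severity, rule code, the offending node and a message.
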