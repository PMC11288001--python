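#!/usr/bin/env python
"""Statistics of the deposited isolate/host records (requires local copies).

Computes, from records placed under data/accessions/ (see
phamily.accession for the expected files), the genome size and G+C of the
isolate phage, its TerL and tail-fiber identities against pelagiphage
homologs, and the host's 16S identity to its nearest named relative.
"""
import json
import sys
from pathlib import Path

from phamily.accession import MissingAccessionData, run_accession_checks

try:
    out = run_accession_checks(Path("data/accessions"))
except MissingAccessionData as exc:
    sys.exit(f"SKIPPED: {exc}")
Path("results").mkdir(exist_ok=True)
Path("results/accession_checks.json").write_text(json.dumps(out, indent=1))
print(json.dumps(out, indent=1))
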