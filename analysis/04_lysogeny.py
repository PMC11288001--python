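#!/usr/bin/env python
"""Integration-site and prophage analysis on a synthetic lysogen.

Builds a Campbell lysogen sharing a 13-bp att core between the phage
(downstream of its tRNA) and the middle of a host tRNA, then recovers the
core (exact maximal matches, tRNA-ranked), the attL/attR junctions from
clipped reads, and the prophage span from chained nucleotide segments.
"""
import json

from phamily import pipeline

r = pipeline.run({"out_dir": "results/run",
                  "stages": {s: s == "lysogeny" for s in pipeline.STAGES}})
print(json.dumps(r.metrics["lysogeny"], indent=1, sort_keys=True))
print("att table: results/run/lysogeny/att_sites.tsv; "
      "prophage calls: results/run/lysogeny/prophages.gff")
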