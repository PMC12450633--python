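"""Generate a synthetic input bundle with planted ground truth.

Writes every table the pipeline consumes (DEG tables, cell metadata,
categorised ATAC peaks, histone narrowPeak tracks, gene annotation, motif
occurrences, pathway sets, enhancer link tables) plus truth.json recording
what was planted.
"""

import json
from pathlib import Path

from hepacre.pipeline import make_fixtures
from hepacre.synthetic import SyntheticConfig

outdir = Path("scratch/example_bundle")
config = SyntheticConfig(seed=42)
paths = make_fixtures(config, outdir)

truth = json.loads(Path(paths["truth"]).read_text())
print(f"wrote {len(paths)} files to {outdir}")
print(f"planted promoters (disease): {len(truth['true_promoters']['HTN'])}")
print(f"planted enhancers (disease): {len(truth['true_enhancers']['HTN'])}")
print(f"planted marker genes: {', '.join(truth['marker_genes'])}")
# The counts are the recovery targets for every downstream example: each
# analysis stage should find exactly these planted elements.
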