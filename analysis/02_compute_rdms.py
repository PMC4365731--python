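#!/usr/bin/env python
"""Compute activation RDMs: per-subject correlation-distance matrices and
their subject average for every region.

Reads results/patterns/, writes results/rdms/<region>.tsv (averaged RDMs)
and reports any subject/region dropped for degenerate (zero-variance)
patterns.
"""

import json
from pathlib import Path

from gramrsa.patterns import read_pattern_manifest, write_rdm_tsv
from gramrsa.pipeline import subject_and_average_rdms

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    patterns = read_pattern_manifest(
        RESULTS / "patterns" / "patterns_manifest.tsv"
    )
    _, averaged, dropped = subject_and_average_rdms(patterns)
    outdir = RESULTS / "rdms"
    outdir.mkdir(parents=True, exist_ok=True)
    for roi_id, rdm in sorted(averaged.items()):
        write_rdm_tsv(rdm, outdir / f"{roi_id}.tsv")
    (outdir / "rdm_manifest.json").write_text(
        json.dumps({"regions": sorted(averaged), "dropped": dropped},
                   indent=2, sort_keys=True)
    )
    print(f"averaged RDMs for {len(averaged)} regions -> {outdir}")
    print(f"dropped subject-region pairs: {len(dropped)}")
    example = sorted(averaged)[0]
    off = averaged[example].upper_vector()
    print(f"example {example}: mean off-diagonal distance "
          f"{off.mean():.3f} (range {off.min():.3f}-{off.max():.3f})")


if __name__ == "__main__":
    main()
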