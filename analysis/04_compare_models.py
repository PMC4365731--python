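#!/usr/bin/env python
"""Subject-level model comparisons: which hypothesis fits better where.

For every region, compares complexity_type vs general_complexity and
detector_phrase vs detector_inflected with the exhaustive sign-flip test on
per-subject statistic differences. Writes results/model_comparisons.tsv and
prints the regions with a significant preference.
"""

from pathlib import Path

import pandas as pd

from gramrsa.design import build_condition_set, build_model
from gramrsa.inference import compare_models
from gramrsa.patterns import activation_rdm, read_pattern_manifest

RESULTS = Path(__file__).resolve().parent.parent / "results"
PAIRS = (
    ("complexity_type", "general_complexity"),
    ("detector_phrase", "detector_inflected"),
)


def main() -> None:
    patterns = read_pattern_manifest(
        RESULTS / "patterns" / "patterns_manifest.tsv"
    )
    cs = build_condition_set()
    by_region: dict[str, list] = {}
    for (subject_id, roi_id), p in sorted(patterns.items()):
        by_region.setdefault(roi_id, []).append(activation_rdm(p))
    rows = []
    for name_a, name_b in PAIRS:
        ma, mb = build_model(name_a, cs), build_model(name_b, cs)
        for region, rdms in sorted(by_region.items()):
            res = compare_models(rdms, ma, mb)
            rows.append({
                "region": region, "model_a": name_a, "model_b": name_b,
                "mean_difference": res.mean_difference, "p": res.p_value,
            })
    comp = pd.DataFrame(rows)
    comp.to_csv(RESULTS / "model_comparisons.tsv", sep="\t", index=False,
                float_format="%.10g")
    print(f"wrote {len(comp)} comparisons -> "
          f"{RESULTS / 'model_comparisons.tsv'}")
    for name_a, name_b in PAIRS:
        sub = comp[(comp.model_a == name_a) & (comp.p < 0.05)]
        better_a = sorted(sub[sub.mean_difference > 0]["region"])
        better_b = sorted(sub[sub.mean_difference < 0]["region"])
        print(f"  {name_a} > {name_b} (p<0.05): {', '.join(better_a) or 'none'}")
        print(f"  {name_b} > {name_a} (p<0.05): {', '.join(better_b) or 'none'}")


if __name__ == "__main__":
    main()
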