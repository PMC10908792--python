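"""Chemical-class coverage of the detected breath metabolome.

Computes, per chemical main class, how many reference-list entries were
actually annotated in the final filtered table versus how many the list
holds, keeping classes with at least 2% of the total hits.
"""

from cohort_common import RESULTS, get_study

import sys
sys.path.insert(0, str(RESULTS.parents[0] / "src"))
from breathomics.coverage import class_coverage, coverage_frame, filter_classes  # noqa: E402


def main():
    reference, data, art, markers = get_study()
    cov = class_coverage(art.table_second_filter, reference)
    kept = filter_classes(cov, min_share=0.02)
    coverage_frame(kept).to_csv(
        RESULTS / "core_metabolome_coverage.tsv", sep="\t", index=False
    )
    total = sum(c.detected for c in cov)
    print(f"core metabolome: {total} class-assigned metabolites; "
          f"{len(kept)}/{len(cov)} classes hold >= 2% of hits")
    for c in kept:
        print(f"  {c.main_class}: {c.detected}/{c.potential} ({c.coverage:.0f}%)")


if __name__ == "__main__":
    main()
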