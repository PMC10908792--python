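"""Gender contrast with the three-method consensus.

Runs the volcano analysis, PLS-DA with VIP scoring and random-forest
classification on the filtered per-subject table, partitions the three
significant sets in a Venn diagram and writes the robust consensus list.
"""

import json

from cohort_common import RESULTS, get_study

import sys
sys.path.insert(0, str(RESULTS.parents[0] / "src"))
from breathomics.pipeline import make_groups  # noqa: E402
from breathomics.stats import consensus  # noqa: E402


def main():
    reference, data, art, markers = get_study()
    groups = make_groups(data.phenotypes, "gender")
    st = art.stats_ready.subset_samples(
        [c for c in art.stats_ready.values.columns if c in groups]
    )
    res = consensus(st, groups, n_trees=500, seed=1)

    res.consensus.head(50).to_csv(RESULTS / "gender_consensus_top.tsv", sep="\t")
    summary = {
        "venn": res.venn,
        "set_sizes": {k: len(v) for k, v in res.sets.items()},
        "rf_oob_error": res.rf.oob_error,
        "rf_confusion": res.rf.confusion.to_dict(),
        "rf_n_predictors": res.rf.n_predictors,
        "plsda_r2y": res.plsda.r2y,
        "plsda_q2y": res.plsda.q2y,
        "n_features": int(st.n_features),
        "n_subjects": int(st.n_samples),
    }
    (RESULTS / "gender_consensus.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n"
    )
    truth = set(markers["gender"])
    feats = art.table_second_filter.features
    core_ids = {feats.loc[f, "db_id"] for f in res.consensus.index}
    print("gender contrast, three-method consensus:")
    print(f"  volcano significant: {len(res.sets['volcano'])}")
    print(f"  PLS-DA VIP>1.5:      {len(res.sets['vip'])}")
    print(f"  RF MDA>0.00016:      {len(res.sets['rf'])}")
    print(f"  all three (ABC):     {res.venn['ABC']}")
    print(f"  RF OOB error {res.rf.oob_error:.4f}, "
          f"PLS-DA R2Y {res.plsda.r2y:.3f} / Q2Y {res.plsda.q2y:.3f}")
    print(f"  planted markers in consensus core: {len(core_ids & truth)}/{len(truth)}")


if __name__ == "__main__":
    main()
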