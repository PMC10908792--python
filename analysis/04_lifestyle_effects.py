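"""Contraceptive and lifestyle contrasts.

Within the female subgroup, compares oral-contraceptive users (FOC) to
non-users (FnOC) with ANOVA + Tukey HSD and a fold-change analysis;
compares alcohol consumers to abstainers with the volcano analysis; and
runs multi-group ANOVA for diet and activity, where no effects were
planted and none should be found.
"""

import json

from cohort_common import RESULTS, get_study

import sys
sys.path.insert(0, str(RESULTS.parents[0] / "src"))
from breathomics.pipeline import make_groups  # noqa: E402
from breathomics.stats import anova_tukey, fold_change, volcano  # noqa: E402


def main():
    reference, data, art, markers = get_study()
    st_all = art.stats_ready
    feats = art.table_second_filter.features
    id_of = {f: feats.loc[f, "db_id"] for f in feats.index}
    out = {}

    # FOC vs FnOC (females only): Tukey HSD + fold change
    foc = make_groups(data.phenotypes, "oc_use")
    st = st_all.subset_samples([c for c in st_all.values.columns if c in foc])
    tuk = anova_tukey(st, foc, alpha=0.1)
    fc = fold_change(st, foc, "FnOC", "FOC")
    sig = tuk[tuk["significant"]].copy()
    sig["fold_change_FnOC_over_FOC"] = fc[sig.index]
    sig["db_id"] = [id_of[f] for f in sig.index]
    sig.sort_values("p_tukey_min").head(25).to_csv(
        RESULTS / "oc_tukey_significant.tsv", sep="\t"
    )
    truth_oc = set(markers.get("oc_use", {}))
    out["oc_use"] = {
        "n_significant": int(sig.shape[0]),
        "n_planted": len(truth_oc),
        "planted_recovered": len(truth_oc & set(sig["db_id"])),
        "groups": {g: list(foc.values()).count(g) for g in set(foc.values())},
    }

    # alcohol: consumers vs abstainers, volcano
    alc = make_groups(data.phenotypes, "alcohol")
    st = st_all.subset_samples([c for c in st_all.values.columns if c in alc])
    v = volcano(st, alc, alpha=0.1)
    vs = v.table[v.table["significant"]].copy()
    vs["db_id"] = [id_of[f] for f in vs.index]
    vs.sort_values("p_adj").head(25).to_csv(
        RESULTS / "alcohol_volcano_significant.tsv", sep="\t"
    )
    truth_alc = set(markers.get("alcohol", {}))
    out["alcohol"] = {
        "n_significant": int(vs.shape[0]),
        "n_planted": len(truth_alc),
        "planted_recovered": len(truth_alc & set(vs["db_id"])),
        "orientation": f"{v.numerator}/{v.denominator}",
    }

    # diet and activity: nothing planted, multi-group ANOVA should be quiet
    for cov in ("diet", "activity"):
        g = make_groups(data.phenotypes, cov, binary=False)
        st = st_all.subset_samples([c for c in st_all.values.columns if c in g])
        res = anova_tukey(st, g, alpha=0.1)
        out[cov] = {"n_significant": int(res["significant"].sum()),
                    "n_features": int(res.shape[0])}

    (RESULTS / "lifestyle_summary.json").write_text(
        json.dumps(out, indent=2) + "\n"
    )
    for cov, d in out.items():
        print(f"{cov}: {d}")


if __name__ == "__main__":
    main()
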