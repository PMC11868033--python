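"""Within-population diversity, Hardy-Weinberg tests, F-statistics, and the
bootstrap neighbor-joining tree over all demes.

The patterns to look for: every lake more diverse than either founder
population (admixture), small negative per-lake F_IS (heterozygote excess
in offspring of mixed parent pools), and pairwise divergence reflecting the
downstream ancestry gradient.
"""

from genmon.diversity import fis, heterozygosity, hwe_exact
from genmon.divergence import bootstrap_tree, wc_fstats

from common import RESULTS, load_state


def main():
    state = load_state()
    gm = state.gm

    div = heterozygosity(gm)
    div.per_locus.to_csv(RESULTS / "diversity_per_locus.tsv", sep="\t", index=False)
    div.means.to_csv(RESULTS / "diversity_means.tsv", sep="\t", index=False)
    print("multi-locus expected heterozygosity by deme:")
    print(div.means[["pop", "He", "Ho", "Ar"]].round(3).to_string(index=False))

    f = fis(gm, n_permutations=2000, seed=1)
    f.drop(columns=["per_locus_f"]).to_csv(RESULTS / "fis.tsv", sep="\t", index=False)
    lake_f = f[f["pop"].str.startswith("Lake")]["f"]
    print(f"\nmean per-lake F_IS = {lake_f.mean():.4f} "
          "(negative = heterozygote excess)")

    hwe = hwe_exact(gm)
    hwe.to_csv(RESULTS / "hwe.tsv", sep="\t", index=False)

    fst = wc_fstats(gm, pairwise=True, n_permutations=199, seed=2)
    fst.per_locus.to_csv(RESULTS / "fstats_per_locus.tsv", sep="\t", index=False)
    fst.pairwise_theta.round(4).to_csv(RESULTS / "pairwise_fst.tsv", sep="\t")
    print(f"\nglobal multi-locus theta (all demes) = {fst.theta:.4f}")
    lakes = [p for p in gm.pops if p.startswith("Lake")]
    sub = fst.pairwise_theta.loc[lakes, lakes].to_numpy()
    import numpy as np
    print(f"among-lake pairwise theta range: "
          f"{sub[np.triu_indices(len(lakes), 1)].min():.3f}"
          f"-{sub[np.triu_indices(len(lakes), 1)].max():.3f}")

    tree = bootstrap_tree(gm, n_bootstrap=1000, seed=3)
    (RESULTS / "nj_tree.nwk").write_text(tree.newick + "\n")
    print(f"\nNJ tree (Nei Da, 1000 locus bootstraps) -> results/nj_tree.nwk")


if __name__ == "__main__":
    main()
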