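"""Community structure: F:B ratios, Bray-Curtis PCoA and PERMANOVA.

Generates paired 16S-like and ITS-like ASV tables plus qPCR gene copies,
then quantifies how strongly the amendment type restructures each domain.
"""

import warnings

from strawcue.community import (
    bray_curtis,
    fb_ratio,
    pcoa_ordination,
    permanova,
    relative_abundance,
    richness,
)
from strawcue.synthetic import (
    ExperimentDesign,
    default_truth,
    generate_asv_tables,
    generate_gene_abundances,
)

warnings.simplefilter("ignore")

design = ExperimentDesign(seed=1)
truth = default_truth(design)
bact, fungi = generate_asv_tables(design, truth)
genes = generate_gene_abundances(design, truth).set_index("sample_id")

fb = fb_ratio(genes["copies_its"], genes["copies_16s"])
genes = genes.assign(fb=fb)
print("Mean F:B ratio (ITS/16S gene copies) per treatment:")
print(genes.groupby("treatment")["fb"].mean().round(4).to_string())

for table in (bact, fungi):
    dist = bray_curtis(relative_abundance(table))
    ordn = pcoa_ordination(dist)
    res = permanova(
        dist, table.sample_metadata.loc[dist.index, "treatment"],
        n_permutations=999, seed=1,
    )
    rich = richness(table)
    print(
        f"\n{table.domain_label}: {table.n_asvs} ASVs, "
        f"median richness {int(rich.median())}"
    )
    print(
        f"  PCoA axis 1/2 explain {100 * ordn.explained[0]:.1f}% / "
        f"{100 * ordn.explained[1]:.1f}% of positive inertia"
    )
    print(
        f"  PERMANOVA by treatment: R2 = {res['r2']:.2f}, "
        f"pseudo-F = {res['pseudo_f']:.1f}, p = {res['p_value']:.3f}"
    )
print(
    "\nA larger fungal than bacterial R2 means the amendments restructure"
    "\nthe fungal community more strongly - the planted behavior here."
)
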