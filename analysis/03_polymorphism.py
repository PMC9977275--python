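"""Within-species polymorphism rates under the coverage filters, plus
within-host temporal change.

Reads results/cohort/, writes results/polymorphism.tsv and
results/polymorphism_change.tsv, and reports that multi-strain hosts carry
higher synonymous polymorphism (the signal the diversity-slope models use).
"""

from pathlib import Path

import pandas as pd

from microdiv import read_cohort
from microdiv.genes import core_genes, high_copy_exclusions
from microdiv.polymorphism import polymorphism_change_table, polymorphism_table

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    tables = read_cohort(ROOT / "cohort")
    core = {sp: core_genes(cn) for sp, cn in tables.genes.items()}
    high = {sp: high_copy_exclusions(cn) for sp, cn in tables.genes.items()}
    poly = polymorphism_table(tables, core, high)
    change = polymorphism_change_table(poly, tables.abundance.meta_frame())
    poly.to_csv(ROOT / "polymorphism.tsv", sep="\t", index=False)
    change.to_csv(ROOT / "polymorphism_change.tsv", sep="\t", index=False)

    truth = pd.read_csv(ROOT / "cohort" / "truth_strains.tsv", sep="\t")
    syn = poly[poly.site_class == "synonymous"].merge(
        truth, on=["sample_id", "species_id"]
    )
    by_k = syn.groupby(syn.K_true > 1)["rate"].median()
    print(
        f"{poly.rate.notna().sum()} defined rates, {len(change)} change pairs; "
        f"median synonymous rate: single-strain {by_k.get(False, float('nan')):.2e}, "
        f"multi-strain {by_k.get(True, float('nan')):.2e}"
    )
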