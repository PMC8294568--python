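#!/usr/bin/env python
"""Generate the synthetic study cohort used by the downstream analyses.

Emits, under results/cohort/: wide SCFA concentration tables for two
visits (study sample-ID layout, dialect A), a QIIME-classic-style OTU
count table with taxonomy, and the planted ground truth (type labels,
true rates) for later comparison.
"""

from pathlib import Path

from mmpkit.data_io import OtuTable, write_otu_table, write_scfa_table
from mmpkit.simulate import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(CohortConfig(seed=SEED))

    write_scfa_table(cohort.series[1], OUT / "scfa_visit1.tsv", dialect="A")
    write_scfa_table(cohort.series[2], OUT / "scfa_visit2.tsv", dialect="A")
    write_otu_table(
        OtuTable(
            sample_ids=list(cohort.otu_counts.index),
            otu_ids=list(cohort.otu_counts.columns),
            counts=cohort.otu_counts.to_numpy(),
            taxonomy=cohort.taxonomy,
        ),
        OUT / "otu_table.tsv",
    )
    cohort.truth.type_labels.to_csv(OUT / "truth_type_labels.tsv", sep="\t")
    for visit, rates in cohort.truth.true_rates.items():
        rates.to_csv(OUT / f"truth_rates_visit{visit}.tsv", sep="\t")

    n = cohort.config.n_donors
    print(f"cohort: {n} donors, 2 visits, {cohort.otu_counts.shape[1]} OTUs")
    print(f"type balance: {cohort.truth.type_labels.value_counts().to_dict()}")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
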