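"""Simulate a small annotated cohort and run the classification cascade.

Generates a two-group cohort of 400 exomes, writes the VCF and companion
tables, reads the VCF back, computes cohort minor-allele frequencies, and
tabulates how many variants each classification flag retains.
"""

import tempfile
from pathlib import Path

from carrierburden import synthetic
from carrierburden.classify import flags_table
from carrierburden.ingest import annotate_cohort_mafs, read_vcf

config = synthetic.SimConfig(
    seed=11,
    groups=(
        synthetic.GroupSpec("european_american", 250, 0.55, 1.0),
        synthetic.GroupSpec("african_american", 150, 0.55, 1.3),
    ),
    n_sf_genes=20,
    n_ar_genes=40,
    n_xlr_genes=10,
)

with tempfile.TemporaryDirectory() as tmp:
    cohort = synthetic.simulate_cohort(config, Path(tmp))
    print(f"wrote {sorted(p.name for p in cohort.paths.values())}")
    variants, samples, warnings = read_vcf(cohort.paths["vcf"])

annotate_cohort_mafs(variants)
flags = flags_table(variants, cohort.transcripts)

print(f"{len(variants)} variants across {len(samples)} samples")
for column in (
    "nonsynonymous",
    "rare",
    "predicted_deleterious",
    "clinvar_pathogenic",
    "hgmd_dm",
    "novel",
):
    print(f"  {column:>22}: {int(flags[column].sum())}")
# Each line counts variants carrying that flag; predicted-deleterious is
# always a subset of the rare nonsynonymous variants, and novel variants
# are those with no record in either control database.
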