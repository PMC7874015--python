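"""Simulate an array-like germplasm panel and run quality control.

Builds the packaged three-generation scenario (clones, selfings, trios,
half-sib clusters through non-genotyped parents), then applies the marker
and individual filters a parentage study would use.
"""

import grapekin as gk

sc = gk.standard_scenario(seed=1)
panel = sc.panel
print(f"simulated panel: {panel.n_samples} individuals x {panel.n_markers} markers")

iq = gk.individual_qc(panel)
print(f"mean individual heterozygosity: {iq['heterozygosity'].mean():.1%}")
# ~33%: the value array panels of outbred, clonally propagated crops show

filtered, marker_report = gk.filter_markers(panel, max_missing=0.01, min_maf=0.05)
print(f"markers kept after missingness/MAF filters: {filtered.n_markers} "
      f"({len(marker_report)} removed)")

strict, indiv_report = gk.filter_individuals(filtered, preset="parentage")
print(f"individuals kept under the parentage preset: {strict.n_samples} "
      f"(removed: {list(indiv_report.index) or 'none'})")
# the selfed offspring S1 is dropped here: its heterozygosity (~17%) falls
# below the 25% floor, exactly as an inbred accession would in a real panel
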