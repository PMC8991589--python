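"""Static documentation of the published candidate-SNP panel decisions.

These constants record, for reference and demos, the selection outcome of a
literature-curated breast-cancer SNP panel for Chinese women: proxy
substitutions chosen at composite r2 > 0.9, SNPs dropped for lack of an
eligible proxy, a tight-LD exclusion, and a validation-panel HWE failure.
Only the substitutions and exclusions stated in the study's main text are
reproduced here; the complete 28-SNP candidate list appeared only in
supplementary material and is not shipped.  The selection operations in
:mod:`prsforge.snpselect` are generic and do not depend on these ids.
"""

#: original -> proxy substitutions (r2 > 0.9)
PROXY_SUBSTITUTIONS = {
    "rs1137101": "rs10789190",
    "rs10941679": "rs4479849",
    "rs662": "rs2057681",
    "rs2234767": "rs7097467",
    "rs2981578": "rs10736303",
    "rs2420946": "rs2162540",
    "rs730154": "rs8031463",
    "rs11655505": "rs9646413",
}

#: candidates excluded because no eligible proxy (r2 > 0.9) was available
DROPPED_NO_PROXY = ["rs1801133", "rs4973768", "rs854560", "rs1695", "rs9282861"]

#: excluded for tight LD (r2 > 0.8) with two retained SNPs
TIGHT_LD_EXCLUDED = {"rs1219648": ("rs2162540", "rs2981575")}

#: failed the validation-panel HWE filter (P < 0.05)
PANEL_HWE_FAILED = ["rs6730484"]

#: additionally removed under the stricter sensitivity pruning (r2 < 0.3)
SENSITIVITY_PRUNED = [
    "rs2981582",
    "rs3803662",
    "rs9646413",
    "rs2162540",
    "rs10736303",
    "rs4479849",
    "rs10789190",
]

#: the interacting pair highlighted by the pairwise scan (LEP / LEPR genes)
INTERACTION_PAIR = ("rs10789190", "rs7799039")
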