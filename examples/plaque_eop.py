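"""Efficiency of plating from a spot-dilution assay.

Simulates a triplicate ten-fold dilution assay for one phage on a defended
strain (true EOP 1e-4) and a strain with no plaques at any dilution, then
computes titers, EOP, log-protection and the protection calls.
"""

from defensekit import simulate as sim
from defensekit.plaque import eop_table

config = sim.PlaqueSimConfig(
    seed=1,
    phage="HK022",
    true_titer_pfu_ml=1e10,
    true_eops=(("defended", 1e-4), ("strongly_defended", 1e-9)),
)
assays, truth = sim.simulate_plaque_assay(config)
table = eop_table(assays, reference_strain=config.reference_strain)

print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
print(
    "eop is the phage titer on each strain relative to the undefended\n"
    "reference (geometric mean over replicates); log_protection = -log10(EOP)\n"
    "is the orders of magnitude of titer reduction. 'protected' requires a\n"
    ">10-fold reduction; 'modest_protection' requires EOP < 0.01 or SFC < 0.5.\n"
    "The strongly defended strain yielded no plaques in some replicates, so\n"
    "its EOP is an upper bound (eop_censored)."
)
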