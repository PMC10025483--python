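"""2^-ddCt fold changes, the signed-FC convention, and anticorrelation.

Simulates a qPCR Ct table with planted fold changes, quantifies them
relative to the ARF1-like reference gene, and classifies miRNA/target
anticorrelation. Also reproduces the printed ABA fold increases.
"""

from mirstress import (
    SimulationConfig,
    correlation_class,
    ddct_fold_change,
    fold_increase,
    load_aba_content,
    signed_fc,
    simulate_ct_tables,
    simulate_srna_libraries,
)

config = SimulationConfig(seed=4, n_mirnas=12, n_transcripts=4, ct_noise_sd=0.15)
sim = simulate_srna_libraries(config)
genes = {"TPS": 3.0, "AP2-like": 0.25}  # planted drought fold changes
table = simulate_ct_tables(config, sim.ground_truth, genes=genes)

print("gene      planted   fc_raw  fc_signed        p")
for gene, planted in genes.items():
    fc = ddct_fold_change(table, gene, ("drought", "control_1"), sim.sample_sheet)
    print(f"{gene:<9} {planted:7.2f}  {fc.fc_raw:7.2f}  {fc.fc_signed:9.2f}  {fc.p:.2e}")
    # TPS rises while its miRNA (miR172b-5p) falls in drought -> anticorrelated
    mirna_call = "down" if gene == "TPS" else "up"
    print(f"          vs miRNA '{mirna_call}': {correlation_class(mirna_call, fc)}")

print(f"\nsigned-FC convention: 0.5 -> {signed_fc(0.5)}, 2.0 -> {signed_fc(2.0)}")

aba = load_aba_content()
print(f"ABA fold increase, drought vs control_1:     "
      f"{fold_increase(aba['drought'], aba['control_1'])}x")
print(f"ABA fold increase, rehydration vs control_2: "
      f"{fold_increase(aba['rehydration'], aba['control_2'])}x")
# Fold changes below 1 are reported as -1/FC so magnitudes are symmetric.
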