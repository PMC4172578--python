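"""Compare detection power across kinship constructions on simulated traits.

Each replicate simulates a trait with known QTNs, scans it with every
method, sets a per-replicate significance threshold from the empirical null
(non-QTN markers), and scores the fraction of QTNs detected.  A small
version of the full study — fewer markers and replicates — so it runs in
seconds.
"""

from supergwas import PopulationModel, PowerStudyConfig, run_power_study

config = PowerStudyConfig(
    model=PopulationModel(
        n_subpops=2,
        fst=0.2,
        chromosomes=[(str(c + 1), 150, 150_000_000) for c in range(5)],
    ),
    n_per_subpop=75,
    n_qtn=10,
    h2=0.75,
    alpha=0.05,
    reps=5,
    seed=44,
    methods=("super-known-qtns", "super", "mlm-all-snps", "mlm-qtn-only"),
)
result = run_power_study(config)
print(result.summary().to_string())
print()
print("reading the table: the trait-specific kinship (super) recovers power"
      "\nthat the all-marker kinship gives up by shrinking true signals,"
      "\nwhile a kinship built from the causal markers themselves"
      "\n(mlm-qtn-only) absorbs the signal almost entirely.")
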