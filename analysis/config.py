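"""Shared study configuration for the analysis scripts.

One synthetic myeloma-like cohort drives scripts 01-07: five SNV
signatures with sparse per-sample mixing, an APOBEC-like signature (S2)
biased to the lagging strand and seeding kataegis foci, a late-replication
tilt for most processes with one early-replicating exception (S4, playing
the role the early-replicating APOBEC component has in real tumors), three
rearrangement signatures, and a karyotype/translocation plan. Script 08
stages a separate cohort with planted signature-defined risk groups.
"""

from pathlib import Path

from myelosig.synthetic import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORT_DIR = RESULTS / "cohort"

SEED = 1

COHORT = SimulationConfig(
    seed=SEED,
    n_samples=60,
    mutations_per_sample=400,
    # 4 Mb of sequence keeps the background inter-mutation spacing (~10 kb)
    # far above the 1-kb kataegis scale, as in real genomes
    contig_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
    n_genes=300,
    n_signatures=5,
    dirichlet_alpha=0.5,
    timing_slope={"S1": 1.0, "S2": 1.0, "S3": 1.0, "S4": -1.0, "S5": 1.0},
    lagging_bias={"S2": 0.7},
    kataegis_rate=0.4,
    kataegis_signature="S2",
    sv_per_sample=25.0,
    n_rs=3,
    hd_fraction=0.3,
)
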