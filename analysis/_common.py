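"""Shared workspace for the numbered analysis drivers.

All drivers operate on one simulated staged-transcriptome scenario
(seed 2026, default sizes: 60 mRNAs, 24 lncRNAs, 12 circRNAs, 16
miRNAs, 6 planted triads over 4 stages x 3 replicates).  The bundle is
regenerated on demand under scratch/ so each script can run on its own;
result tables go to results/.
"""

from __future__ import annotations

from pathlib import Path

from cernapipe.simulate import GroundTruth, ScenarioConfig, simulate_scenario

ROOT = Path(__file__).resolve().parents[1]
BUNDLE_DIR = ROOT / "scratch" / "analysis_bundle"
RESULTS_DIR = ROOT / "results"
SEED = 2026

SCENARIO = ScenarioConfig(seed=SEED)


def ensure_bundle() -> tuple[dict[str, Path], GroundTruth]:
    """Simulate the shared scenario if it is not already on disk."""
    truth_path = BUNDLE_DIR / "truth.json"
    if truth_path.exists():
        names = ["genome.fa", "annotation.gff3", "transcripts.fa", "mirnas.fa",
                 "counts_mrna.tsv", "counts_lncrna.tsv", "counts_circrna.tsv",
                 "counts_mirna.tsv", "reads.fa", "terms.tsv", "truth.json"]
        return ({n: BUNDLE_DIR / n for n in names},
                GroundTruth.from_json(truth_path))
    return simulate_scenario(SCENARIO, BUNDLE_DIR)


def results_path(name: str) -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    return RESULTS_DIR / name
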