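"""Shared plumbing for the numbered analysis drivers.

The drivers analyse one deterministic synthetic study (seed 1, default
design).  Heavy intermediates live under scratch/ (regenerable), distilled
tables under results/.
"""

from __future__ import annotations

from pathlib import Path

from binmeth.quantify import MethylationProfile, profile_from_coverage
from binmeth.synthetic import SyntheticConfig, generate_dataset

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study_seed1"
RESULTS = ROOT / "results"
SEED = 1


def study_config() -> SyntheticConfig:
    return SyntheticConfig(seed=SEED)


def dataset_dir() -> Path:
    """Generate (once) and return the synthetic study directory."""
    if not (SCRATCH / "samples.tsv").exists():
        generate_dataset(study_config(), SCRATCH)
    return SCRATCH


def load_profiles() -> dict[str, MethylationProfile]:
    root = dataset_dir()
    profiles = {}
    for line in (root / "samples.tsv").read_text().splitlines()[1:]:
        sample, rel, cell, age = line.split("\t")
        profiles[sample] = profile_from_coverage(
            root / rel, sample, age=age, cell_type=cell, is_path=True
        )
    return profiles


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
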