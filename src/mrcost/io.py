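"""Plain-text interchange formats.

Summary statistics travel as tab-separated text with the fixed header
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, pval, n``;
cohorts as one-row-per-individual TSV with genotype columns named by snp
id; every written artifact gets a JSON sidecar recording the config and
seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .assoc import SUMMARY_COLUMNS
from .cohort import Cohort
from .simulate import SnpPanel

__all__ = [
    "write_summary_stats",
    "read_summary_stats",
    "write_cohort",
    "read_cohort",
    "write_panel",
    "read_panel",
    "write_sidecar",
]


def write_summary_stats(frame: pd.DataFrame, path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    frame[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    return frame


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    cohort.to_frame().to_csv(path, sep="\t", index=False)
    cohort.snp_info.to_csv(path.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_cohort(path) -> Cohort:
    path = Path(path)
    snp_info = pd.read_csv(path.with_suffix(".snps.tsv"), sep="\t")
    return Cohort.from_frame(pd.read_csv(path, sep="\t"), snp_info)


def write_panel(panel: SnpPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path) -> SnpPanel:
    return SnpPanel.from_frame(pd.read_csv(path, sep="\t"))


def write_sidecar(path, config: dict, seed) -> None:
    """JSON metadata sidecar next to a written artifact."""
    meta = {"artifact": str(Path(path).name), "seed": seed, "config": config}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
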