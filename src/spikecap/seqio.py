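"""FASTA and design-config loading."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import yaml
from Bio import SeqIO

from spikecap.design import (
    DesignError,
    GSPDesign,
    ReadAnatomy,
    TargetGene,
    parse_gsp,
)

__all__ = [
    "read_target_fasta",
    "write_target_fasta",
    "load_design_config",
]


def read_target_fasta(path: Union[str, Path], name: Optional[str] = None) -> TargetGene:
    """Load the first (and only) record of a FASTA file as a target."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DesignError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise DesignError(f"{path}: expected a single target, found {len(records)}")
    rec = records[0]
    return TargetGene(name=name or rec.id, sequence=str(rec.seq))


def write_target_fasta(target: TargetGene, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write(f">{target.name}\n")
        seq = target.sequence
        for i in range(0, len(seq), 70):
            handle.write(seq[i : i + 70] + "\n")


def load_design_config(
    path: Union[str, Path], target: Optional[TargetGene] = None
) -> tuple[GSPDesign, ReadAnatomy]:
    """Read a YAML/JSON design config.

    Either an explicit ``oligo`` (with ``adaptor`` and ``feature_barcode``
    literals to segment it) or the full segment fields may be given.  Anatomy
    fields are optional and default to the 10x 5' layout.
    """
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise DesignError(f"{path}: design config must be a mapping")

    anatomy_cfg = cfg.get("anatomy", {})
    anatomy = ReadAnatomy(**anatomy_cfg)

    if "oligo" in cfg:
        design = parse_gsp(cfg["oligo"], cfg["adaptor"], cfg["feature_barcode"])
    else:
        design = GSPDesign(
            adaptor=cfg["adaptor"],
            spacer1_len=int(cfg.get("spacer1_len", 10)),
            feature_barcode=cfg["feature_barcode"],
            spacer2_len=int(cfg.get("spacer2_len", 9)),
            target_anchor=cfg["target_anchor"],
        )
    if target is not None:
        design = design.locate_anchor(target)
    return design, anatomy
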