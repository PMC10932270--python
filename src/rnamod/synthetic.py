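"""Synthetic planted-motif benchmark generator.

Positives are background sequences into which the non-wildcard bases of a
wildcard motif (e.g. ``U.AAU``; ``.`` = any base) are written near the window
center, at an offset jittered uniformly within a small radius; negatives are
pure i.i.d. background. Because the planted signal and its positions are
known exactly, classifier performance, attention-based interpretability and
cross-dataset transfer can all be checked against ground truth without any
external data.

Wildcard positions are left as background draws and are not forced to differ
from the motif consensus (a deliberately simple null model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import Dataset, SequenceRecord, write_fasta_dataset

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "write_dataset",
    "generate_species_family",
]

_RNA = "ACGU"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 41-nt windows (the most common window length among published
    site predictors), uniform base composition, motif ``U.AAU`` always planted
    (plant_prob = 1) within +/-3 nt of the center.
    """

    n_pos: int = 200
    n_neg: int = 200
    length: int = 41
    motif: str = "U.AAU"
    plant_prob: float = 1.0
    offset_jitter: int = 3
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError("plant_prob must lie in [0, 1]")
        if set(self.motif) - set(_RNA + "."):
            raise ValueError(f"motif must be over {{A,C,G,U,.}}: {self.motif!r}")
        if self.motif.count(".") == len(self.motif):
            raise ValueError("motif needs at least one non-wildcard position")
        if self.length < len(self.motif) + 2 * self.offset_jitter:
            raise ValueError(
                "window too short: length must be >= motif width + 2*offset_jitter"
            )
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


@dataclass
class GroundTruth:
    """Per-record planted flag and planted start position (None if unplanted)."""

    planted: dict[str, int | None] = field(default_factory=dict)

    def motif_positions(self, record_id: str, motif: str) -> list[int]:
        """Non-wildcard sequence positions of the planted motif, if any."""
        start = self.planted.get(record_id)
        if start is None:
            return []
        return [start + i for i, ch in enumerate(motif) if ch != "."]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tplanted_start\n")
            for rid, start in self.planted.items():
                fh.write(f"{rid}\t{'' if start is None else start}\n")


def _random_sequence(rng: np.random.Generator, length: int, composition) -> list[str]:
    return list(rng.choice(list(_RNA), size=length, p=list(composition)))


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Generate one labeled dataset plus its planting ground truth (seeded)."""
    rng = np.random.default_rng(spec.seed)
    width = len(spec.motif)
    center_start = spec.length // 2 - width // 2
    records: list[SequenceRecord] = []
    truth = GroundTruth()

    for i in range(spec.n_pos):
        rid = f"{spec.name}_pos_{i}"
        seq = _random_sequence(rng, spec.length, spec.composition)
        jitter = int(rng.integers(-spec.offset_jitter, spec.offset_jitter + 1))
        plant = rng.random() < spec.plant_prob
        if plant:
            start = center_start + jitter
            for j, ch in enumerate(spec.motif):
                if ch != ".":
                    seq[start + j] = ch
            truth.planted[rid] = start
        else:
            truth.planted[rid] = None
        records.append(SequenceRecord(id=rid, sequence="".join(seq), label=1))

    for i in range(spec.n_neg):
        rid = f"{spec.name}_neg_{i}"
        seq = _random_sequence(rng, spec.length, spec.composition)
        truth.planted[rid] = None
        records.append(SequenceRecord(id=rid, sequence="".join(seq), label=0))

    return Dataset(records, name=spec.name), truth


def write_dataset(
    dataset: Dataset, truth: GroundTruth, out_dir, spec: SyntheticSpec | None = None
) -> dict[str, Path]:
    """Write FASTA + label TSV + ground-truth TSV (+ spec echo) to a directory.

    Ground truth goes to a sidecar file, never into FASTA headers, so a model
    reading the FASTA cannot leak planting information.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{dataset.name}.fasta",
        "labels": out_dir / f"{dataset.name}.labels.tsv",
        "truth": out_dir / f"{dataset.name}.truth.tsv",
    }
    write_fasta_dataset(dataset, paths["fasta"], paths["labels"])
    truth.to_tsv(paths["truth"])
    if spec is not None:
        import yaml

        paths["spec"] = out_dir / f"{dataset.name}.spec.yaml"
        with open(paths["spec"], "w") as fh:
            yaml.safe_dump(asdict(spec), fh)
    return paths


def generate_species_family(
    base_spec: SyntheticSpec, motif_map
) -> list[tuple[Dataset, GroundTruth]]:
    """One dataset per pseudo-species, each with its own motif.

    ``motif_map`` is a mapping or an iterable of (name, motif) pairs. Species
    sharing a motif emulate sequence-level conservation within a taxonomy;
    distinct motifs emulate divergence across taxonomies. Each species gets a
    distinct derived seed.
    """
    pairs = list(motif_map.items()) if hasattr(motif_map, "items") else list(motif_map)
    if len(pairs) < 2:
        raise ValueError("a species family needs at least two entries")
    names = [name for name, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")
    out = []
    for i, (name, motif) in enumerate(pairs):
        spec = SyntheticSpec(
            **{
                **asdict(base_spec),
                "name": name,
                "motif": motif,
                "seed": base_spec.seed + 1000 * (i + 1),
            }
        )
        out.append(generate(spec))
    return out
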