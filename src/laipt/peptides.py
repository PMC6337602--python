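"""Peptide-window extraction around candidate lysines.

Acetylation happens on the lysine side chain, so every candidate sample is a
fixed-width sequence window of length 2n+1 centered on a K residue, with
signed offsets -n..+n (0 at the lysine).  Windows overhanging a terminus are
padded with 'X', which downstream encoders treat as a zero-property residue,
so all feature vectors share one dimensionality.

Datasets pair positively annotated lysine windows with (optionally
subsampled) unannotated-lysine windows.  Input sequences are expected to be
redundancy-reduced upstream (e.g. CD-HIT at 40% identity); no clustering is
done here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Non-standard codes collapsed to the unknown residue on ingest.
AMBIGUOUS_TO_X = {"B", "Z", "U", "O", "J"}
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

Label = Literal["positive", "negative", "unlabeled"]


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r} contains invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class SiteAnnotation:
    """An experimentally proven acetylated lysine, 1-based position."""

    protein_id: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("annotation positions are 1-based (>= 1)")


@dataclass(frozen=True)
class WindowSpec:
    """Half-width n of the sliding window; full length is 2n+1."""

    half_width: int

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)


@dataclass(frozen=True)
class PeptideWindow:
    residues: str
    label: Label
    protein_id: str
    position: int  # 1-based position of the central lysine in its protein

    @property
    def half_width(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def center(self) -> str:
        return self.residues[self.half_width]

    @property
    def offsets(self) -> np.ndarray:
        n = self.half_width
        return np.arange(-n, n + 1)


@dataclass
class LabeledDataset:
    windows: list[PeptideWindow]
    spec: WindowSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.windows:
            if len(w.residues) != self.spec.window_length:
                raise ValueError(
                    f"window {w.protein_id}:{w.position} has length "
                    f"{len(w.residues)}, expected {self.spec.window_length}"
                )
        keys = [(w.protein_id, w.position) for w in self.windows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (protein_id, position) pairs in dataset")

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if w.label == "positive" else 0 for w in self.windows])

    @property
    def n_positive(self) -> int:
        return sum(w.label == "positive" for w in self.windows)

    @property
    def n_negative(self) -> int:
        return sum(w.label == "negative" for w in self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def sanitize_sequence(raw: str, source_id: str = "?") -> str:
    """Uppercase and map non-standard residue codes to 'X'."""
    seq = raw.upper()
    out = []
    warned: set[str] = set()
    for ch in seq:
        if ch in ALPHABET:
            out.append(ch)
        else:
            if ch not in warned:
                logger.warning("protein %s: residue %r mapped to 'X'", source_id, ch)
                warned.add(ch)
            out.append("X")
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; the FASTA header token becomes the id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_sites(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV with header columns protein_id, position."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return [
        SiteAnnotation(protein_id=str(r.protein_id), position=int(r.position))
        for r in df.itertuples()
    ]


def write_sites(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(s.protein_id, s.position) for s in sites],
        columns=["protein_id", "position"],
    ).to_csv(path, sep="\t", index=False)


def extract_window(sequence: str, position: int, spec: WindowSpec) -> str:
    """The 2n+1 residues centered at a 1-based position, 'X'-padded at termini."""
    i = position - 1
    n = spec.half_width
    left = sequence[max(0, i - n) : i]
    right = sequence[i + 1 : i + 1 + n]
    return "X" * (n - len(left)) + left + sequence[i] + right + "X" * (n - len(right))


def extract_windows(protein: ProteinRecord, spec: WindowSpec) -> list[PeptideWindow]:
    """One unlabeled window per lysine in the sequence."""
    out = []
    for i, ch in enumerate(protein.sequence):
        if ch == "K":
            out.append(
                PeptideWindow(
                    residues=extract_window(protein.sequence, i + 1, spec),
                    label="unlabeled",
                    protein_id=protein.id,
                    position=i + 1,
                )
            )
    return out


def build_dataset(
    proteins: list[ProteinRecord],
    annotations: list[SiteAnnotation],
    spec: WindowSpec,
    negative_ratio: float | str = 1.0,
    seed: int = 0,
    on_bad_annotation: Literal["error", "skip"] = "error",
) -> LabeledDataset:
    """Label lysine windows from annotations and subsample negatives.

    Annotated (protein, position) pairs become positives; every other lysine
    window is a negative candidate.  Negatives are then drawn without
    replacement down to ``negative_ratio`` x positives with the given seed
    ("all" keeps every candidate).  Annotations pointing outside a sequence
    or at a non-K residue raise by default, listing the offenders.
    """
    by_id = {p.id: p for p in proteins}
    bad: list[str] = []
    positive_keys: set[tuple[str, int]] = set()
    for ann in annotations:
        prot = by_id.get(ann.protein_id)
        if prot is None:
            bad.append(f"{ann.protein_id}:{ann.position} (unknown protein)")
            continue
        if ann.position > len(prot.sequence):
            bad.append(f"{ann.protein_id}:{ann.position} (past sequence end)")
            continue
        if prot.sequence[ann.position - 1] != "K":
            bad.append(
                f"{ann.protein_id}:{ann.position} "
                f"(residue {prot.sequence[ann.position - 1]!r}, expected 'K')"
            )
            continue
        positive_keys.add((ann.protein_id, ann.position))
    if bad:
        msg = f"{len(bad)} invalid annotations: " + "; ".join(bad[:10])
        if on_bad_annotation == "error":
            raise ValueError(msg)
        logger.warning("%s (skipped)", msg)

    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    for prot in proteins:
        for w in extract_windows(prot, spec):
            if (w.protein_id, w.position) in positive_keys:
                positives.append(replace(w, label="positive"))
            else:
                negatives.append(replace(w, label="negative"))

    n_candidates = len(negatives)
    if negative_ratio != "all":
        ratio = float(negative_ratio)
        if ratio <= 0:
            raise ValueError("negative_ratio must be positive or 'all'")
        n_keep = min(n_candidates, int(round(ratio * len(positives))))
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_candidates, size=n_keep, replace=False)
        negatives = [negatives[i] for i in np.sort(idx)]

    return LabeledDataset(
        windows=positives + negatives,
        spec=spec,
        provenance={
            "n_positive": len(positives),
            "n_negative": len(negatives),
            "n_negative_candidates": n_candidates,
            "negative_ratio": negative_ratio,
            "seed": seed,
        },
    )


def trim_dataset(dataset: LabeledDataset, spec: WindowSpec) -> LabeledDataset:
    """Narrow every window to a smaller half-width, keeping labels."""
    if spec.half_width > dataset.spec.half_width:
        raise ValueError("can only trim to a smaller half-width")
    delta = dataset.spec.half_width - spec.half_width
    windows = [
        replace(w, residues=w.residues[delta : len(w.residues) - delta])
        for w in dataset.windows
    ]
    prov = dict(dataset.provenance)
    prov["trimmed_from_half_width"] = dataset.spec.half_width
    return LabeledDataset(windows=windows, spec=spec, provenance=prov)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    pd.DataFrame(
        [(w.protein_id, w.position, w.residues, w.label) for w in dataset.windows],
        columns=["protein_id", "position", "window", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t")
    windows = [
        PeptideWindow(
            residues=str(r.window),
            label=str(r.label),
            protein_id=str(r.protein_id),
            position=int(r.position),
        )
        for r in df.itertuples()
    ]
    if not windows:
        raise ValueError(f"dataset file {path} is empty")
    n = (len(windows[0].residues) - 1) // 2
    return LabeledDataset(windows=windows, spec=WindowSpec(half_width=n))
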