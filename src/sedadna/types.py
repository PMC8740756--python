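"""Shared domain types: aligned fragments, reference panels, block layouts."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

SPOT_CATEGORIES = (
    "regular",
    "micro",
    "bone",
    "coprolite",
    "matrix",
    "inorganic",
    "untargeted",
)


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced fragment placed on a reference.

    ``pairs`` holds (reference base, read base) per aligned column, in read
    orientation: for a minus-strand placement both members are already
    reverse-complemented, so terminal damage is counted in read coordinates
    regardless of strand. Gap columns use ``-`` on the gapped side.
    ``start``/``end`` are 0-based half-open on the linearised reference; a
    placement crossing the origin of a circular reference sets ``wraps``.
    """

    fragment_id: str
    spot_id: str
    reference_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    pairs: tuple[tuple[str, str], ...]
    mapping_score: float = 60.0
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        n_ref = sum(1 for r, _ in self.pairs if r != "-")
        if not self.wraps and self.end - self.start != n_ref:
            raise ValueError(
                f"{self.fragment_id}: end-start={self.end - self.start} "
                f"inconsistent with {n_ref} reference-consuming columns"
            )
        for r, q in self.pairs:
            if r not in VALID_BASES | {"-"} or q not in VALID_BASES | {"-"}:
                raise ValueError(f"invalid base pair ({r}, {q})")

    @property
    def length(self) -> int:
        """Read length in bases (gap columns on the read side excluded)."""
        return sum(1 for _, q in self.pairs if q != "-")

    @property
    def read_sequence(self) -> str:
        return "".join(q for _, q in self.pairs if q != "-")


@dataclass(frozen=True)
class SamplingSpot:
    """A drilled sampling location on a block face. Coordinates in mm."""

    spot_id: str
    x_mm: float
    y_mm: float
    mass_mg: float
    category: str = "regular"
    layer: str = ""

    def __post_init__(self) -> None:
        if self.category not in SPOT_CATEGORIES:
            raise ValueError(f"unknown spot category {self.category!r}")


@dataclass
class BlockLayout:
    """Sampling geometry of one block face.

    ``area_cm2`` is the sampled surface area a used by the nearest-neighbor
    index; it is an explicit input (convex hull vs full face is a recording
    choice made at the scanner, not recoverable from spot coordinates).
    """

    spots: list[SamplingSpot]
    area_cm2: float

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ValueError("spot ids must be unique")
        if not self.area_cm2 > 0:
            raise ValueError("area_cm2 must be positive")

    def __len__(self) -> int:
        return len(self.spots)

    def spot(self, spot_id: str) -> SamplingSpot:
        for s in self.spots:
            if s.spot_id == spot_id:
                return s
        raise KeyError(spot_id)

    def coordinates_cm(self) -> "pd.DataFrame":
        """Spot coordinates converted mm → cm, indexed by spot_id."""
        return pd.DataFrame(
            {
                "x_cm": [s.x_mm / 10.0 for s in self.spots],
                "y_cm": [s.y_mm / 10.0 for s in self.spots],
            },
            index=pd.Index([s.spot_id for s in self.spots], name="spot_id"),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "spot_id": s.spot_id,
                    "x_mm": s.x_mm,
                    "y_mm": s.y_mm,
                    "mass_mg": s.mass_mg,
                    "category": s.category,
                    "layer": s.layer,
                }
                for s in self.spots
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["area_cm2"] = self.area_cm2
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, area_cm2: float | None = None) -> "BlockLayout":
        df = pd.read_csv(path, sep="\t")
        if area_cm2 is None:
            if "area_cm2" not in df.columns:
                raise ValueError("area_cm2 column missing and no explicit area given")
            area_cm2 = float(df["area_cm2"].iloc[0])
        spots = [
            SamplingSpot(
                spot_id=str(r.spot_id),
                x_mm=float(r.x_mm),
                y_mm=float(r.y_mm),
                mass_mg=float(r.mass_mg),
                category=str(r.category),
                layer="" if pd.isna(r.layer) else str(r.layer),
            )
            for r in df.itertuples()
        ]
        return cls(spots=spots, area_cm2=area_cm2)


@dataclass
class ReferencePanel:
    """Mitogenome panel with a two-rank species → family taxonomy.

    Genomes are circular; callers that scan them linearise with a wrap
    margin (see :func:`sedadna.profiling.linearize`).
    """

    genomes: dict[str, str]
    taxonomy: dict[str, str]  # species_id -> family

    def __post_init__(self) -> None:
        missing = set(self.genomes) - set(self.taxonomy)
        if missing:
            raise ValueError(f"species without family: {sorted(missing)}")
        for sp, seq in self.genomes.items():
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"genome {sp} contains non-ACGT characters")

    @property
    def species(self) -> list[str]:
        return sorted(self.genomes)

    @property
    def families(self) -> list[str]:
        return sorted(set(self.taxonomy.values()))

    def family_of(self, species_id: str) -> str:
        return self.taxonomy[species_id]

    def write(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.genomes[sp]), id=sp, description="")
            for sp in self.species
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        pd.DataFrame(
            {"species_id": self.species,
             "family": [self.taxonomy[sp] for sp in self.species]}
        ).to_csv(taxonomy_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, taxonomy_path: str | Path) -> "ReferencePanel":
        genomes = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        tax = pd.read_csv(taxonomy_path, sep="\t")
        taxonomy = dict(zip(tax["species_id"].astype(str), tax["family"].astype(str)))
        return cls(genomes=genomes, taxonomy=taxonomy)


def write_fragments_fasta(path: str | Path, fragments: Iterable[tuple[str, str]]) -> None:
    """Write (fragment_id, sequence) pairs as an uncompressed FASTA."""
    records = [SeqRecord(Seq(seq), id=fid, description="") for fid, seq in fragments]
    SeqIO.write(records, str(path), "fasta")


def read_fragments_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def fragments_to_tsv(fragments: Sequence[AlignedFragment], path: str | Path) -> None:
    """Serialise aligned fragments to the internal tabular format.

    The paired-base string interleaves reference and read bases column by
    column (CIGAR-free), e.g. ``CT`` for one C→T column.
    """
    rows = []
    for f in fragments:
        rows.append(
            {
                "fragment_id": f.fragment_id,
                "spot_id": f.spot_id,
                "ref_id": f.reference_id,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "mapping_score": f.mapping_score,
                "wraps": int(f.wraps),
                "pairs": "".join(r + q for r, q in f.pairs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def fragments_from_sam(path: str | Path, spot_of=None) -> list[AlignedFragment]:
    """Thin SAM reader: mapped reads with MD tags → aligned fragments.

    Pairs are reconstructed from CIGAR+MD via pysam and reoriented to read
    coordinates for minus-strand alignments (terminal damage is counted on
    the read). Unmapped and secondary records are skipped. ``spot_of`` maps
    read name → spot id; defaults to the ``<spot>|<index>`` convention.
    """
    import pysam

    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            pairs = []
            for qpos, _, ref_base in rec.get_aligned_pairs(with_seq=True):
                q = seq[qpos].upper() if qpos is not None else "-"
                r = ref_base.upper() if ref_base is not None else "-"
                pairs.append((r, q))
            if rec.is_reverse:
                pairs = [(r.translate(comp), q.translate(comp))
                         for r, q in reversed(pairs)]
            name = rec.query_name
            spot = (spot_of or {}).get(name, name.split("|")[0])
            out.append(
                AlignedFragment(
                    fragment_id=name,
                    spot_id=spot,
                    reference_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    pairs=tuple(pairs),
                    mapping_score=float(rec.mapping_quality),
                )
            )
    return out


def fragments_from_tsv(path: str | Path) -> list[AlignedFragment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        s = str(r.pairs)
        pairs = tuple((s[i], s[i + 1]) for i in range(0, len(s), 2))
        out.append(
            AlignedFragment(
                fragment_id=str(r.fragment_id),
                spot_id=str(r.spot_id),
                reference_id=str(r.ref_id),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                pairs=pairs,
                mapping_score=float(r.mapping_score),
                wraps=bool(r.wraps),
            )
        )
    return out
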