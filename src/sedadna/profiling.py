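"""Family-level taxonomic assignment and per-spot composition profiles.

Fragments are aligned ungapped against every panel mitogenome in both
orientations: exact k-mer seeds propose placements on a wrap-margin
linearisation of the circular reference, candidate placements are scored
by mismatch count with numpy, and a full sliding-window scan guarantees
correctness whenever seeding cannot (pigeonhole bound). Ungapped scoring
is deliberate — an edit-distance aligner converts terminal C→T mismatches
into end gaps of equal cost and thereby erases the deamination signal the
downstream authentication relies on.

All species within a fixed mismatch margin of the best score are collected
and collapsed by lowest common ancestor over the two-rank species→family
taxonomy: a family is emitted only when every candidate belongs to it and
the best identity clears ``identity_min`` — the conservative MEGAN-style
behaviour, without BLAST statistics.

Profiles normalise counts per milligram of sediment (optionally using the
resin-corrected effective mass) and attach per-family ancient-origin flags
from the damage module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from sedadna.damage import (
    ancient_origin_test,
    is_deaminated,
    terminal_profile,
)
from sedadna.types import AlignedFragment, BlockLayout, ReferencePanel

UNASSIGNED = "unassigned"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALN_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _revcomp_aln(s: str) -> str:
    """Reverse-complement an aligned string, gaps staying gaps."""
    return s.translate(_ALN_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AssignParams:
    """Assignment knobs. ``margin`` is in mismatches: all species within
    ``margin`` of the best mismatch count are kept for the LCA step.
    ``wrap_margin`` bases of the genome start are appended to the
    linearised reference so fragments crossing the origin still align
    (must be at least the longest fragment). ``seed_k`` is the exact-seed
    length; placements with at most floor(len/k) − 1 mismatches are
    guaranteed to be seeded, anything weaker falls back to a full scan
    when it could matter."""

    margin: int = 1
    identity_min: float = 0.90
    wrap_margin: int = 500
    seed_k: int = 8


def linearize(genome: str, wrap_margin: int) -> str:
    m = min(wrap_margin, len(genome))
    return genome + genome[:m]


@dataclass
class AssignmentResult:
    fragment_id: str
    spot_id: str
    species: tuple[str, ...]          # all candidates within the margin
    family: str                       # family name or UNASSIGNED
    identity: float
    edit_distance: int
    aligned: AlignedFragment | None = None

    @property
    def assigned(self) -> bool:
        return self.family != UNASSIGNED


# base encoding: A/C/G/T -> 0..3, anything else 4 (mismatches everything)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """4-ary k-mer codes per offset; −1 where the window has a non-ACGT base."""
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(arr, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win.astype(np.int64) @ powers
    codes[(win >= 4).any(axis=1)] = -1
    return codes


class _GenomeIndex:
    """Seeded ungapped search over one linearised circular genome."""

    def __init__(self, genome: str, wrap_margin: int, k: int) -> None:
        self.length = len(genome)
        self.lin = linearize(genome, wrap_margin)
        self.arr = _encode(self.lin)
        self.k = k
        codes = _kmer_codes(self.arr, k)
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = order.astype(np.int64)

    def _candidate_offsets(self, query: np.ndarray) -> np.ndarray:
        qcodes = _kmer_codes(query, self.k)
        valid = np.flatnonzero(qcodes >= 0)
        if valid.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._sorted_codes, qcodes[valid], "left")
        hi = np.searchsorted(self._sorted_codes, qcodes[valid], "right")
        offs = [self._sorted_pos[l:h] - q for q, l, h in zip(valid, lo, hi)]
        offs = np.unique(np.concatenate(offs)) if offs else np.empty(0, np.int64)
        n = len(query)
        return offs[(offs >= 0) & (offs + n <= self.arr.size) & (offs < self.length)]

    def _score_offsets(self, query: np.ndarray, offs: np.ndarray):
        sub = self.arr[offs[:, None] + np.arange(len(query))[None, :]]
        mm = (sub != query[None, :]).sum(axis=1)
        i = int(mm.argmin())
        return int(mm[i]), int(offs[i])

    def seeded_best(self, query: np.ndarray) -> tuple[int, int] | None:
        """(mismatches, offset) of the best seeded placement, or None."""
        offs = self._candidate_offsets(query)
        if offs.size == 0:
            return None
        return self._score_offsets(query, offs)

    def scan_best(self, query: np.ndarray) -> tuple[int, int]:
        """Exact best placement by full sliding-window comparison."""
        n = len(query)
        if n > self.arr.size:
            raise ValueError("fragment longer than the linearised reference")
        win = sliding_window_view(self.arr, n)
        stop = min(self.length, win.shape[0])
        mm = (win[:stop] != query[None, :]).sum(axis=1)
        i = int(mm.argmin())
        return int(mm[i]), i


class PanelAligner:
    """Ungapped best-hit search of fragments against a reference panel.

    Builds one k-mer index per genome; reuse the instance across fragments.
    """

    def __init__(self, panel: ReferencePanel, params: AssignParams | None = None):
        self.panel = panel
        self.params = params or AssignParams()
        self._index = {
            sp: _GenomeIndex(panel.genomes[sp], self.params.wrap_margin,
                             self.params.seed_k)
            for sp in panel.species
        }

    def best_hits(self, seq: str) -> dict[str, tuple[int, int, str]]:
        """Per species: (mismatches, start offset, strand) of its best
        placement, exact for every species that could lie within the LCA
        margin of the overall best."""
        p = self.params
        queries = {"+": _encode(seq), "-": _encode(_revcomp(seq))}
        hits: dict[str, tuple[int, int, str]] = {}
        exact: dict[str, bool] = {}
        guarantee = len(seq) // p.seed_k - 1
        for sp, index in self._index.items():
            best = None
            for strand, q in queries.items():
                r = index.seeded_best(q)
                if r is not None and (best is None or r[0] < best[0]):
                    best = (r[0], r[1], strand)
            if best is not None:
                hits[sp] = best
                exact[sp] = best[0] <= guarantee
            else:
                exact[sp] = False
        if hits:
            threshold = min(mm for mm, _, _ in hits.values()) + p.margin
        else:
            threshold = np.inf
        for sp, index in self._index.items():
            needs_scan = not exact[sp] and (
                sp not in hits or guarantee + 1 <= threshold
            )
            if needs_scan:
                best = None
                for strand, q in queries.items():
                    mm, off = index.scan_best(q)
                    if best is None or mm < best[0]:
                        best = (mm, off, strand)
                hits[sp] = best
        return hits


def _aligned_fragment(
    fragment_id: str,
    spot_id: str,
    seq: str,
    species: str,
    index: _GenomeIndex,
    offset: int,
    strand: str,
    mapping_score: float,
) -> AlignedFragment:
    """Substitution-only (reference base, read base) pairs in read orientation."""
    n = len(seq)
    ref_slice = index.lin[offset:offset + n]
    if strand == "+":
        pairs = tuple(zip(ref_slice, seq))
    else:
        # the reverse-complemented read matched the forward reference;
        # express both in read orientation
        pairs = tuple(zip(_revcomp(ref_slice), seq))
    L = index.length
    start = offset % L
    end = start + n
    return AlignedFragment(
        fragment_id=fragment_id,
        spot_id=spot_id,
        reference_id=species,
        start=start,
        end=end,
        strand=strand,
        pairs=pairs,
        mapping_score=mapping_score,
        wraps=end > L,
    )


def assign_fragment(
    fragment_id: str,
    seq: str,
    panel: ReferencePanel,
    params: AssignParams | None = None,
    spot_id: str = "",
    build_alignment: bool = True,
    aligner: PanelAligner | None = None,
) -> AssignmentResult:
    """Assign one fragment to a family by score-margin LCA.

    Tie handling is order-free: candidates are collected as the set of
    species within the margin, and the representative alignment is built
    against the lexicographically first best-scoring species. Pass a
    prebuilt :class:`PanelAligner` when assigning many fragments.
    """
    if aligner is None:
        aligner = PanelAligner(panel, params)
    params = aligner.params
    seq = seq.upper()
    hits = aligner.best_hits(seq)
    best = min(mm for mm, _, _ in hits.values())
    candidates = tuple(sorted(sp for sp, (mm, _, _) in hits.items()
                              if mm <= best + params.margin))
    identity = 1.0 - best / len(seq) if len(seq) else 0.0
    families = {panel.family_of(sp) for sp in candidates}
    if identity < params.identity_min or len(families) != 1:
        family = UNASSIGNED
    else:
        (family,) = families
    # MAPQ-like score: unique species hit 60, within-family tie 37,
    # cross-family ambiguity 0
    if len(candidates) == 1:
        score = 60.0
    elif len(families) == 1:
        score = 37.0
    else:
        score = 0.0
    aligned = None
    if build_alignment:
        rep = min(sp for sp, (mm, _, _) in hits.items() if mm == best)
        _, offset, strand = hits[rep]
        aligned = _aligned_fragment(
            fragment_id, spot_id, seq, rep, aligner._index[rep],
            offset, strand, score,
        )
    return AssignmentResult(
        fragment_id=fragment_id,
        spot_id=spot_id,
        species=candidates,
        family=family,
        identity=identity,
        edit_distance=best,
        aligned=aligned,
    )


def assign_all(
    fragments: Sequence[tuple[str, str]],
    panel: ReferencePanel,
    params: AssignParams | None = None,
    spot_of: Mapping[str, str] | None = None,
) -> list[AssignmentResult]:
    """Assign many (fragment_id, sequence) pairs.

    Spot ids default to the header convention ``<spot_id>|<index>`` used by
    the synthetic generator; pass ``spot_of`` to override.
    """
    aligner = PanelAligner(panel, params)
    out = []
    for fid, seq in fragments:
        spot = spot_of[fid] if spot_of else fid.split("|")[0]
        out.append(
            assign_fragment(fid, seq, panel, spot_id=spot, aligner=aligner)
        )
    return out


def assignments_to_frame(results: Sequence[AssignmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fragment_id": r.fragment_id,
                "spot_id": r.spot_id,
                "family": r.family,
                "species": ",".join(r.species),
                "identity": r.identity,
                "edit_distance": r.edit_distance,
                "deaminated": is_deaminated(r.aligned) if r.aligned else False,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# per-spot family profiles

@dataclass
class FamilyCount:
    n_fragments: int
    n_deaminated: int
    fragments_per_mg: float
    ancient_flag: bool


@dataclass
class FamilyProfile:
    """Per-spot family composition; families with zero fragments omitted."""

    spot_id: str
    mass_mg: float
    families: dict[str, FamilyCount] = field(default_factory=dict)

    @property
    def n_identified(self) -> int:
        return sum(c.n_fragments for c in self.families.values())


def build_family_profiles(
    results: Sequence[AssignmentResult],
    layout: BlockLayout,
    effective_mass_mg: Mapping[str, float] | None = None,
    ancient_threshold: float = 0.10,
) -> dict[str, FamilyProfile]:
    """Collapse assignments into per-spot, per-family profiles.

    Per-milligram yields use ``effective_mass_mg`` (resin-corrected, from
    the quantification stage) when provided, else the drilled spot mass.
    The ancient flag per (spot, family) comes from the two-ended terminal
    C→T test run on that group's alignments. Every layout spot appears in
    the output, empty profiles included.
    """
    known_spots = {s.spot_id for s in layout.spots}
    for r in results:
        if r.spot_id not in known_spots:
            raise KeyError(f"assignment references unknown spot {r.spot_id!r}")
    masses = {
        s.spot_id: (effective_mass_mg or {}).get(s.spot_id, s.mass_mg)
        for s in layout.spots
    }
    if any(m <= 0 for m in masses.values()):
        raise ValueError("spot masses must be positive")

    profiles = {
        s.spot_id: FamilyProfile(spot_id=s.spot_id, mass_mg=masses[s.spot_id])
        for s in layout.spots
    }
    grouped: dict[tuple[str, str], list[AssignmentResult]] = {}
    for r in results:
        if r.assigned:
            grouped.setdefault((r.spot_id, r.family), []).append(r)
    for (spot_id, family), members in sorted(grouped.items()):
        aligned = [m.aligned for m in members if m.aligned is not None]
        n_deam = sum(is_deaminated(a) for a in aligned)
        verdict = ancient_origin_test(
            terminal_profile(aligned, "5p", 1),
            terminal_profile(aligned, "3p", 1),
            threshold=ancient_threshold,
        )
        profiles[spot_id].families[family] = FamilyCount(
            n_fragments=len(members),
            n_deaminated=n_deam,
            fragments_per_mg=len(members) / masses[spot_id],
            ancient_flag=verdict.is_ancient,
        )
    return profiles


def profiles_to_frame(profiles: Mapping[str, FamilyProfile]) -> pd.DataFrame:
    """Tidy TSV-ready table; spots with no assigned fragments get one row
    with family NA so they remain visible in reports."""
    rows = []
    for spot_id in sorted(profiles):
        p = profiles[spot_id]
        if not p.families:
            rows.append({"spot_id": spot_id, "family": pd.NA, "n_fragments": 0,
                         "n_deaminated": 0, "fragments_per_mg": 0.0,
                         "ancient_flag": False, "mass_mg": p.mass_mg})
        for fam in sorted(p.families):
            c = p.families[fam]
            rows.append({"spot_id": spot_id, "family": fam,
                         "n_fragments": c.n_fragments,
                         "n_deaminated": c.n_deaminated,
                         "fragments_per_mg": c.fragments_per_mg,
                         "ancient_flag": c.ancient_flag, "mass_mg": p.mass_mg})
    return pd.DataFrame(rows)


def dominant_families(profile: FamilyProfile, fraction: float = 0.10) -> set[str]:
    """Families holding at least ``fraction`` of the spot's identified
    fragments (boundary inclusive: exactly 10% counts as dominant)."""
    total = profile.n_identified
    if total == 0:
        return set()
    return {
        fam for fam, c in profile.families.items()
        if c.n_fragments / total >= fraction
    }


def taxa_richness(
    profile: FamilyProfile,
    require_ancient: bool = True,
    min_count: int = 1,
) -> int:
    """Number of families detected at the spot (optionally ancient-only)."""
    return sum(
        1 for c in profile.families.values()
        if c.n_fragments >= min_count and (c.ancient_flag or not require_ancient)
    )
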