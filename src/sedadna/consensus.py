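"""mtDNA consensus building, distances, neighbor joining and lineage calls.

Consensus genomes are reconstructed from deaminated fragments only (the
damage filter removes present-day contamination). The calling rule is the
classic conservative majority rule for ancient mtDNA: a base is called at
a position iff it is covered by at least two unique fragments and at least
66% of them agree; everything else is N. Internal consistency — evidence
for more than one contributing mtDNA — is assessed at well-covered
positions (≥10 fragments) where consensus support falls below 80%, with a
check of whether the minor allele sits near fragment ends (the signature
of residual deamination rather than a second individual).

Distances are pairwise differences over co-called positions; trees are
built by canonical Saitou–Nei neighbor joining with non-parametric
bootstrap over alignment columns. Hominin lineage assignment counts
fragment votes at diagnostic positions, excluding sites confounded by
C→T/G→A damage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sedadna.damage import binomial_ci
from sedadna.types import AlignedFragment

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN-", "TGCAN-")


def _reference_oriented(f: AlignedFragment) -> list[tuple[str, str]]:
    """Alignment columns in forward-reference orientation.

    AlignedFragment stores pairs in read orientation (what damage counting
    needs); minus-strand placements are complemented and reversed here so
    pileup bases agree with the forward reference strand.
    """
    if f.strand == "+":
        return list(f.pairs)
    return [(r.translate(_COMP), q.translate(_COMP)) for r, q in reversed(f.pairs)]


# ---------------------------------------------------------------------------
# pileup

@dataclass
class FragmentPileup:
    reference_id: str
    length: int
    counts: np.ndarray            # (L, 4) A/C/G/T from unique fragments
    end_proximal: np.ndarray      # (L, 4) observations within 3 read bases of an end
    fragment_ids: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _dedupe(fragments: Sequence[AlignedFragment]) -> list[AlignedFragment]:
    """Collapse duplicates: identical (start, end, strand, read sequence)."""
    seen = set()
    out = []
    for f in sorted(fragments, key=lambda f: f.fragment_id):
        key = (f.start, f.end, f.strand, f.read_sequence)
        if key not in seen:
            seen.add(key)
            out.append(f)
    return out


def build_pileup(
    fragments: Sequence[AlignedFragment],
    reference_id: str,
    reference_length: int,
    dedupe: bool = True,
    end_window: int = 3,
) -> FragmentPileup:
    """Per-position base counts on a circular reference.

    Fragments must lie within the reference unless flagged as wrapping the
    origin; wrapped coordinates are folded back modulo the length.
    """
    counts = np.zeros((reference_length, 4), dtype=np.int64)
    near = np.zeros((reference_length, 4), dtype=np.int64)
    uniq = _dedupe(fragments) if dedupe else list(fragments)
    for f in uniq:
        if f.end > reference_length and not f.wraps:
            raise ValueError(
                f"{f.fragment_id} extends past the reference without wrap flag"
            )
        cols = _reference_oriented(f)
        n_read = sum(1 for _, q in cols if q != "-")
        read_i = 0
        pos = f.start
        for r, q in cols:
            if r == "-":          # insertion in read: no reference position
                if q != "-":
                    read_i += 1
                continue
            p = pos % reference_length
            if q in _BASE_INDEX:
                counts[p, _BASE_INDEX[q]] += 1
                # distance-to-nearer-end is symmetric, so read vs reference
                # orientation does not matter here
                if min(read_i, n_read - 1 - read_i) < end_window:
                    near[p, _BASE_INDEX[q]] += 1
            if q != "-":
                read_i += 1
            pos += 1
    return FragmentPileup(
        reference_id=reference_id,
        length=reference_length,
        counts=counts,
        end_proximal=near,
        fragment_ids=[f.fragment_id for f in uniq],
    )


# ---------------------------------------------------------------------------
# consensus

@dataclass
class ConsensusSequence:
    """Per-position calls with coverage and support; N where uncalled."""

    name: str
    calls: np.ndarray     # (L,) unicode bases incl N
    coverage: np.ndarray  # (L,) int
    support: np.ndarray   # (L,) float, NaN at zero coverage

    @property
    def covered_fraction(self) -> float:
        return float(np.mean(self.calls != "N"))

    @property
    def sequence(self) -> str:
        return "".join(self.calls)

    def to_fasta(self, path: str | Path) -> None:
        Path(path).write_text(f">{self.name}\n{self.sequence}\n")


def call_consensus(
    pileup: FragmentPileup,
    min_cov: int = 2,
    majority: float = 0.66,
    name: str | None = None,
) -> ConsensusSequence:
    """Majority-rule consensus: coverage ≥ ``min_cov`` and modal-base
    fraction ≥ ``majority`` (boundary inclusive: 2 of 3 = 66.7% calls);
    multi-modal ties give N."""
    cov = pileup.coverage
    calls = np.full(pileup.length, "N", dtype="U1")
    support = np.full(pileup.length, np.nan)
    nonzero = cov > 0
    if nonzero.any():
        top = pileup.counts[nonzero].max(axis=1)
        support[nonzero] = top / cov[nonzero]
        modal = pileup.counts[nonzero].argmax(axis=1)
        tie = (pileup.counts[nonzero] == top[:, None]).sum(axis=1) > 1
        ok = (cov[nonzero] >= min_cov) & (support[nonzero] >= majority) & ~tie
        idx = np.flatnonzero(nonzero)
        calls[idx[ok]] = _BASES[modal[ok]]
    return ConsensusSequence(
        name=name or pileup.reference_id,
        calls=calls,
        coverage=cov,
        support=support,
    )


@dataclass
class FlaggedPosition:
    position: int
    coverage: int
    support: float
    minor_end_proximal_fraction: float  # minor-allele obs within 3 bases of an end


def internal_consistency(
    pileup: FragmentPileup,
    min_cov: int = 10,
    support_threshold: float = 0.80,
) -> list[FlaggedPosition]:
    """Flag well-covered positions with weak consensus support.

    Positions covered by ≥ ``min_cov`` fragments whose modal-base fraction
    is < ``support_threshold`` indicate either a second mtDNA or residual
    terminal damage; ``minor_end_proximal_fraction`` reports how much of
    the minor-allele evidence lies within three bases of fragment ends
    (≈1 favours the damage explanation).
    """
    cov = pileup.coverage
    flagged = []
    for p in np.flatnonzero(cov >= min_cov):
        top_i = int(pileup.counts[p].argmax())
        support = pileup.counts[p, top_i] / cov[p]
        if support < support_threshold:
            minor_total = int(cov[p] - pileup.counts[p, top_i])
            minor_near = int(
                pileup.end_proximal[p].sum() - pileup.end_proximal[p, top_i]
            )
            flagged.append(
                FlaggedPosition(
                    position=int(p),
                    coverage=int(cov[p]),
                    support=float(support),
                    minor_end_proximal_fraction=(
                        minor_near / minor_total if minor_total else np.nan
                    ),
                )
            )
    return flagged


# ---------------------------------------------------------------------------
# distances

def pairwise_differences(
    cons_a: ConsensusSequence | str, cons_b: ConsensusSequence | str
) -> tuple[int, int]:
    """(differences, co-called sites) over positions non-N in both."""
    a = np.array(list(cons_a.sequence if isinstance(cons_a, ConsensusSequence)
                      else cons_a), dtype="U1")
    b = np.array(list(cons_b.sequence if isinstance(cons_b, ConsensusSequence)
                      else cons_b), dtype="U1")
    if a.size != b.size:
        raise ValueError("sequences must share coordinates (equal length)")
    both = (a != "N") & (b != "N")
    n_compared = int(both.sum())
    if n_compared == 0:
        raise ValueError("no co-called positions: distance undefined")
    return int(np.sum(a[both] != b[both])), n_compared


def distance_matrix(
    sequences: Mapping[str, ConsensusSequence | str],
    normalised: bool = True,
) -> pd.DataFrame:
    """Symmetric distance matrix (p-distance by default) over co-called sites."""
    labels = sorted(sequences)
    D = np.zeros((len(labels), len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        diff, comp = pairwise_differences(sequences[labels[i]],
                                          sequences[labels[j]])
        D[i, j] = D[j, i] = diff / comp if normalised else diff
    return pd.DataFrame(D, index=labels, columns=labels)


def write_phylip(D: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(D)}\n")
        for label in D.index:
            row = " ".join(f"{v:.6f}" for v in D.loc[label])
            fh.write(f"{label}  {row}\n")


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c, _ in self.children))

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{c._newick_inner()}:{bl:.6f}" for c, bl in self.children
        )
        return f"({inner})"


def neighbor_joining(
    D: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric zero-diagonal matrix.

    Ties in the Q criterion are broken by sorted label order, so the
    result is independent of input row order. Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch, keeping
    the path length between the joined pair equal to their distance.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        M = D.to_numpy(dtype=float).copy()
    else:
        M = np.asarray(D, dtype=float).copy()
        labels = list(labels) if labels is not None else [
            f"t{i}" for i in range(len(M))
        ]
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(M) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")

    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    # sort key per working node: min leaf label, for deterministic ties
    keys = [l for l in labels]

    if n == 2:
        root = TreeNode()
        root.children = [(nodes[0], float(M[0, 1])), (nodes[1], 0.0)]
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = M[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break: smallest (key_i, key_j) among minima
        cand = np.argwhere(np.isclose(Q, qmin))
        best = min(
            (tuple(sorted((keys[active[i]], keys[active[j]]))), (i, j))
            for i, j in cand if i < j
        )[1]
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        new = TreeNode()
        pair = sorted(
            [(nodes[ai], li, keys[ai]), (nodes[aj], lj, keys[aj])],
            key=lambda t: t[2],
        )
        new.children = [(pair[0][0], pair[0][1]), (pair[1][0], pair[1][1])]
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (M[ai, :] + M[aj, :] - dij)
        M[ai, :] = dnew
        M[:, ai] = dnew
        M[ai, ai] = 0.0
        nodes[ai] = new
        keys[ai] = min(keys[ai], keys[aj])
        active.pop(j)

    a, b, c = active
    # final star: closed-form branch lengths
    la = 0.5 * (M[a, b] + M[a, c] - M[b, c])
    lb = 0.5 * (M[a, b] + M[b, c] - M[a, c])
    lc = 0.5 * (M[a, c] + M[b, c] - M[a, b])
    branches = [(nodes[a], max(la, 0.0), keys[a]),
                (nodes[b], max(lb, 0.0), keys[b]),
                (nodes[c], max(lc, 0.0), keys[c])]
    branches.sort(key=lambda t: t[2])
    root = TreeNode()
    root.children = [(nd, bl) for nd, bl, _ in branches]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalised as the
    side not containing the alphabetically first leaf."""
    all_leaves = tree.leaves()
    ref = min(all_leaves)
    parts: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c, _ in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            parts.add(side)
        return below

    for child, _ in tree.children:
        walk(child)
    return parts


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 500,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Bootstrap support (percent of replicates) per internal bipartition.

    Columns of the aligned sequences (N allowed) are resampled with
    replacement; each replicate's distance matrix and NJ tree are rebuilt
    from scratch. Needs ≥4 taxa and ≥2 variable columns.
    """
    labels = sorted(alignment)
    if len(labels) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    arr = np.array([list(alignment[l]) for l in labels], dtype="U1")
    n_cols = arr.shape[1]
    informative = ~np.all(arr == arr[0], axis=0)
    if informative.sum() < 2:
        raise ValueError("fewer than 2 variable columns: support undefined")

    def tree_from(cols: np.ndarray) -> TreeNode:
        seqs = {l: "".join(cols[i]) for i, l in enumerate(labels)}
        return neighbor_joining(distance_matrix(seqs))

    original = bipartitions(tree_from(arr))
    hits = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(n_cols, size=n_cols)
        try:
            reps = bipartitions(tree_from(arr[:, idx]))
        except ValueError:  # replicate with no co-called sites for some pair
            continue
        for bp in hits:
            if bp in reps:
                hits[bp] += 1
    return {bp: 100.0 * k / n_reps for bp, k in hits.items()}


# ---------------------------------------------------------------------------
# lineage assignment

@dataclass(frozen=True)
class DiagnosticSite:
    position: int                 # 0-based on the mtDNA reference
    alleles: tuple[tuple[str, str], ...]  # (lineage, base)

    def lineage_states(self) -> dict[str, str]:
        return dict(self.alleles)


@dataclass
class DiagnosticPanel:
    """Positions whose allele state separates hominin mtDNA lineages
    (modern human, Neanderthal, Denisovan, Sima de los Huesos)."""

    sites: list[DiagnosticSite]

    def __post_init__(self) -> None:
        for s in self.sites:
            if len(set(b for _, b in s.alleles)) < 2:
                raise ValueError(
                    f"site {s.position} has fewer than 2 distinct states"
                )

    @property
    def lineages(self) -> list[str]:
        names = set()
        for s in self.sites:
            names.update(l for l, _ in s.alleles)
        return sorted(names)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"position": s.position, "lineage": l, "base": b}
            for s in self.sites for l, b in s.alleles
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiagnosticPanel":
        df = pd.read_csv(path, sep="\t")
        sites = []
        for pos, grp in df.groupby("position"):
            sites.append(DiagnosticSite(
                position=int(pos),
                alleles=tuple(sorted(zip(grp["lineage"], grp["base"]))),
            ))
        return cls(sites=sorted(sites, key=lambda s: s.position))


def _damage_confounded(site: DiagnosticSite) -> bool:
    states = {b for _, b in site.alleles}
    return {"C", "T"} <= states or {"G", "A"} <= states


def _base_at(fragment: AlignedFragment, ref_position: int,
             reference_length: int) -> str | None:
    """Read base (forward-reference orientation) at a reference position."""
    pos = fragment.start
    for r, q in _reference_oriented(fragment):
        if r == "-":
            continue
        if pos % reference_length == ref_position:
            return q if q in _BASE_INDEX else None
        pos += 1
    return None


@dataclass
class LineageCall:
    call: str                      # lineage name, "mixed" or "undetermined"
    votes: dict[str, int]
    n_informative: int
    ci: tuple[float, float] | None
    n_sites_used: int
    n_sites_excluded: int


def assign_lineage(
    fragments: Sequence[AlignedFragment],
    panel: DiagnosticPanel,
    reference_length: int,
    exclude_damage_confounded: bool = True,
) -> LineageCall:
    """Call the mtDNA lineage by fragment votes at diagnostic positions.

    A fragment overlapping a diagnostic site votes for every lineage whose
    state matches its base; fragments matching all lineages (or none) are
    uninformative. Sites whose discriminating substitution is C↔T or G↔A
    are excluded by default because deamination mimics them. The call is
    the majority lineage (>50% of informative votes) with a Wilson CI on
    its vote share; an exact split is reported as "mixed".
    """
    if not panel.sites:
        raise ValueError("diagnostic panel is empty")
    used = [
        s for s in panel.sites
        if not (exclude_damage_confounded and _damage_confounded(s))
    ]
    votes: dict[str, int] = {l: 0 for l in panel.lineages}
    n_informative = 0
    for frag in fragments:
        for site in used:
            base = _base_at(frag, site.position, reference_length)
            if base is None:
                continue
            states = site.lineage_states()
            matching = [l for l, b in states.items() if b == base]
            if not matching or len(matching) == len(states):
                continue
            n_informative += 1
            for l in matching:
                votes[l] += 1
    if n_informative == 0:
        return LineageCall("undetermined", votes, 0, None,
                           len(used), len(panel.sites) - len(used))
    top = max(votes.values())
    leaders = sorted(l for l, v in votes.items() if v == top)
    ci = binomial_ci(top, n_informative)
    if top * 2 > n_informative and len(leaders) == 1:
        call = leaders[0]
    elif top * 2 == n_informative:
        call = "mixed"
    else:
        call = "undetermined"
    return LineageCall(call, votes, n_informative, ci,
                       len(used), len(panel.sites) - len(used))
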