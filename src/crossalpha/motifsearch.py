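"""Multi-segment backbone-motif search and database curation.

This is the "designability" pipeline: curate a non-redundant structure
database, define a small (possibly two-chain) backbone motif — here, the
seven-residue RxxxR helix fragment plus the five-residue C-terminal fragment
of a laterally docked helix, or an axial-stacking control of the same size —
search the database for sub-cutoff backbone-RMSD placements under one joint
rigid superposition, filter matches for sequence redundancy, and summarize
them as RMSD-divergence curves and per-position amino-acid (logo) counts.

The search enumerates candidate windows per segment with an admissible bound
(a segment's own optimal RMSD can never exceed ``cutoff * sqrt(A_total/A_seg)``
if the joint RMSD is within ``cutoff``), prunes segment combinations whose
inter-segment centroid distances are incompatible with the query, and scores
the survivors exactly — so it returns precisely the matches a brute-force
enumeration would.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter

import numpy as np
import pandas as pd

from .helixgeom import superpose
from .structio import Structure

__all__ = [
    "DatabaseFilter",
    "SearchDatabase",
    "MotifSegment",
    "MotifQuery",
    "MotifMatch",
    "DivergenceCurve",
    "LogoCounts",
    "sequence_identity",
    "filter_database",
    "cluster_chains",
    "select_nonredundant_biounits",
    "define_motif",
    "save_motif",
    "load_motif",
    "search_motif",
    "redundancy_filter",
    "divergence_curve",
    "logo_counts",
]

BACKBONE = ("N", "CA", "C", "O")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# database curation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DatabaseFilter:
    """Criteria a biological unit must meet to enter the search database."""

    max_resolution: float = 2.6
    min_protein_fraction: float = 0.60
    max_residues: int = 5000
    max_chains: int = 26
    xray_only: bool = True

    def __post_init__(self) -> None:
        if min(self.max_resolution, self.min_protein_fraction,
               self.max_residues, self.max_chains) <= 0:
            raise ValueError("all filter thresholds must be positive")


def filter_database(structures: list[Structure], f: DatabaseFilter
                    ) -> tuple[list[Structure], Counter]:
    """Retain structures meeting every criterion; count rejection reasons.

    Resolution and experimental method come from ``Structure.meta``
    (``resolution``, ``method``); a missing required field rejects the entry
    with reason ``missing-metadata`` rather than raising. The resolution bound
    is inclusive ("2.6 Å or better"). Protein fraction uses
    ``meta['protein_fraction']`` when present, else 1.0 (the parser only
    retains amino-acid residues, so parsed content is all-protein).
    """
    retained, reasons = [], Counter()
    for s in structures:
        res = s.meta.get("resolution")
        if res is None:
            reasons["missing-metadata"] += 1
            continue
        if f.xray_only:
            method = s.meta.get("method")
            if method is None:
                reasons["missing-metadata"] += 1
                continue
            if "x-ray" not in method.lower().replace("xray", "x-ray"):
                reasons["not-xray"] += 1
                continue
        if res > f.max_resolution:
            reasons["resolution"] += 1
            continue
        if s.meta.get("protein_fraction", 1.0) < f.min_protein_fraction:
            reasons["protein-fraction"] += 1
            continue
        if s.n_residues > f.max_residues:
            reasons["too-many-residues"] += 1
            continue
        if len(s.chains) > f.max_chains:
            reasons["too-many-chains"] += 1
            continue
        retained.append(s)
    return retained, reasons


def _aligner():
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical pairs / alignment length."""
    if not a or not b:
        return 0.0
    aln = _aligner().align(a, b)[0]
    matches = 0
    length = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        frag_a, frag_b = a[s1:e1], b[s2:e2]
        matches += sum(x == y for x, y in zip(frag_a, frag_b))
    # alignment length includes gaps on either side
    length = aln.length if hasattr(aln, "length") else max(len(a), len(b))
    return matches / length


def cluster_chains(chains: list[str], identity: float = 0.5) -> list[int]:
    """Greedy centroid clustering of sequences at a global-identity threshold.

    Chains are visited longest-first; each joins the first existing cluster
    whose representative shares at least ``identity``, else founds a new one.
    Deterministic given the input order. Returns one cluster id per input, in
    input order.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must lie in (0, 1]")
    order = sorted(range(len(chains)), key=lambda i: (-len(chains[i]), i))
    reps: list[str] = []
    ids = [0] * len(chains)
    for i in order:
        for cid, rep in enumerate(reps):
            if sequence_identity(chains[i], rep) >= identity:
                ids[i] = cid
                break
        else:
            ids[i] = len(reps)
            reps.append(chains[i])
    return ids


def select_nonredundant_biounits(biounits: list[Structure],
                                 cluster_ids: dict[str, tuple[int, ...]]
                                 ) -> list[Structure]:
    """Drop biological units whose chain-cluster multiset is covered.

    A unit A is eliminated iff some unit B holds a strict superset of A's
    chain-cluster multiset, or holds an equal multiset with better (lower)
    resolution — ids break remaining ties. The outcome is independent of
    input order.
    """
    def multiset(s: Structure) -> Counter:
        return Counter(cluster_ids[s.id])

    def priority(s: Structure) -> tuple:
        return (s.meta.get("resolution", float("inf")), s.id)

    msets = {s.id: multiset(s) for s in biounits}
    retained = []
    for a in biounits:
        ma = msets[a.id]
        eliminated = False
        for b in biounits:
            if b.id == a.id:
                continue
            mb = msets[b.id]
            if all(mb[k] >= v for k, v in ma.items()):
                if mb != ma or priority(b) < priority(a):
                    eliminated = True
                    break
        if not eliminated:
            retained.append(a)
    return retained


@dataclasses.dataclass
class SearchDatabase:
    """Curated, cluster-annotated structures plus backbone coordinate index."""

    entries: list[Structure]
    chain_clusters: dict[str, tuple[int, ...]]  # entry id -> per-chain cluster

    @classmethod
    def build(cls, structures: list[Structure],
              f: DatabaseFilter | None = None,
              identity: float = 0.5) -> "SearchDatabase":
        """Filter, cluster chains, and keep a minimally non-redundant subset."""
        f = f or DatabaseFilter()
        kept, _ = filter_database(structures, f)
        seqs, owners = [], []
        for s in kept:
            for c in s.chains:
                seqs.append(c.sequence)
                owners.append(s.id)
        ids = cluster_chains(seqs, identity)
        clusters: dict[str, list[int]] = {s.id: [] for s in kept}
        for owner, cid in zip(owners, ids):
            clusters[owner].append(cid)
        cluster_map = {k: tuple(v) for k, v in clusters.items()}
        nonred = select_nonredundant_biounits(kept, cluster_map)
        return cls(nonred, {s.id: cluster_map[s.id] for s in nonred})


# ---------------------------------------------------------------------------
# motif definition and search
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifSegment:
    length: int
    backbone: np.ndarray  # (length, 4, 3): N, CA, C, O per residue
    sequence: str
    source: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, float)
        if self.backbone.shape != (self.length, 4, 3):
            raise ValueError("backbone must be (length, 4, 3)")


@dataclasses.dataclass
class MotifQuery:
    segments: list[MotifSegment]
    source: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("motif needs at least one segment")
        if any(seg.length < 3 for seg in self.segments):
            raise ValueError("each segment needs at least 3 residues")
        if self.n_residues < 5:
            raise ValueError("motif needs at least 5 residues in total")

    @property
    def n_residues(self) -> int:
        return sum(seg.length for seg in self.segments)

    @property
    def n_atoms(self) -> int:
        return 4 * self.n_residues

    def stacked(self) -> np.ndarray:
        return np.concatenate([seg.backbone.reshape(-1, 3)
                               for seg in self.segments])


def define_motif(s: Structure, segments: list[tuple[str, int, int]]
                 ) -> MotifQuery:
    """Extract a motif query from (chain_id, start_seq_id, length) selections."""
    out = []
    for chain_id, start, length in segments:
        if length < 1:
            raise ValueError("zero-length motif segment")
        chain = s.chain(chain_id)
        bb, seq = [], []
        for sid in range(start, start + length):
            r = chain.residue(sid)
            row = []
            for nm in BACKBONE:
                if not r.has_atom(nm):
                    raise ValueError(
                        f"residue {chain_id}/{r.aa}{sid} lacks backbone atom {nm}")
                row.append(r.atom(nm).position)
            bb.append(row)
            seq.append(r.aa)
        out.append(MotifSegment(length, np.array(bb), "".join(seq),
                                {"structure": s.id, "chain": chain_id,
                                 "start": start}))
    return MotifQuery(out, {"structure": s.id})


def save_motif(q: MotifQuery, path) -> None:
    """Write a motif query as JSON (backbone coordinates in Å)."""
    import json

    doc = {"source": q.source,
           "segments": [{"length": seg.length, "sequence": seg.sequence,
                         "source": seg.source,
                         "backbone": seg.backbone.tolist()}
                        for seg in q.segments]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_motif(path) -> MotifQuery:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    segs = [MotifSegment(d["length"], np.array(d["backbone"]),
                         d["sequence"], d.get("source", {}))
            for d in doc["segments"]]
    return MotifQuery(segs, doc.get("source", {}))


@dataclasses.dataclass
class MotifMatch:
    entry_id: str
    placements: list[tuple[str, int]]  # (chain_id, start seq_id) per segment
    rmsd: float
    sequences: list[str]

    def sort_key(self) -> tuple:
        return (self.rmsd, self.entry_id, tuple(self.placements))


def _chain_windows(chain) -> tuple[np.ndarray, list[int]]:
    """Backbone array (L,4,3) and seq_ids for residues with full backbones."""
    bb, sids = [], []
    for r in chain.residues:
        if all(r.has_atom(nm) for nm in BACKBONE):
            bb.append([r.atom(nm).position for nm in BACKBONE])
            sids.append(r.seq_id)
    return np.array(bb, float).reshape(-1, 4, 3), sids


def _candidate_windows(entry: Structure, seg: MotifSegment, bound: float
                       ) -> list[tuple[str, int, int, np.ndarray]]:
    """(chain_id, start_index, start_seq_id, coords) windows under the bound.

    Windows must be contiguous in author numbering (no chain breaks).
    """
    q = seg.backbone.reshape(-1, 3)
    out = []
    for chain in entry.chains:
        bb, sids = _chain_windows(chain)
        n = len(sids)
        for i in range(0, n - seg.length + 1):
            if sids[i + seg.length - 1] - sids[i] != seg.length - 1:
                continue
            w = bb[i:i + seg.length].reshape(-1, 3)
            if superpose(w, q).rmsd <= bound:
                out.append((chain.chain_id, i, sids[i], w))
    return out


def _overlap(a: tuple, b: tuple, la: int, lb: int) -> bool:
    (ca, _, sa, _), (cb, _, sb, _) = a, b
    if ca != cb:
        return False
    return sa < sb + lb and sb < sa + la


def search_motif(db: SearchDatabase | list[Structure], q: MotifQuery,
                 rmsd_cutoff: float = 1.0) -> list[MotifMatch]:
    """Every placement of the query with joint backbone RMSD ≤ cutoff.

    A placement assigns each segment an ungapped residue window; segments may
    sit on different chains of the same entry but may not overlap each other.
    Matches are sorted by ascending RMSD (ties: entry id, placements). The
    cutoff is inclusive.
    """
    if rmsd_cutoff <= 0:
        raise ValueError("rmsd cutoff must be positive")
    entries = db.entries if isinstance(db, SearchDatabase) else list(db)
    a_total = q.n_atoms
    seg_bounds = [rmsd_cutoff * np.sqrt(a_total / (4 * seg.length))
                  for seg in q.segments]
    q_stacked = q.stacked()
    q_centroids = [seg.backbone.reshape(-1, 3).mean(axis=0)
                   for seg in q.segments]
    matches: list[MotifMatch] = []
    for entry in entries:
        cand = [_candidate_windows(entry, seg, b)
                for seg, b in zip(q.segments, seg_bounds)]
        if any(not c for c in cand):
            continue
        for combo in itertools.product(*cand):
            ok = True
            for si, sj in itertools.combinations(range(len(combo)), 2):
                if _overlap(combo[si], combo[sj],
                            q.segments[si].length, q.segments[sj].length):
                    ok = False
                    break
                d_q = np.linalg.norm(q_centroids[si] - q_centroids[sj])
                ci = combo[si][3].mean(axis=0)
                cj = combo[sj][3].mean(axis=0)
                slack = rmsd_cutoff * (np.sqrt(a_total / (4 * q.segments[si].length))
                                       + np.sqrt(a_total / (4 * q.segments[sj].length)))
                if abs(np.linalg.norm(ci - cj) - d_q) > slack:
                    ok = False
                    break
            if not ok:
                continue
            w = np.concatenate([c[3] for c in combo])
            r = superpose(w, q_stacked).rmsd
            if r <= rmsd_cutoff:
                placements = [(c[0], c[2]) for c in combo]
                seqs = []
                for (cid, sid), seg in zip(placements, q.segments):
                    chain = entry.chain(cid)
                    seqs.append("".join(
                        chain.residue(s).aa
                        for s in range(sid, sid + seg.length)))
                matches.append(MotifMatch(entry.id, placements, float(r), seqs))
    matches.sort(key=MotifMatch.sort_key)
    return matches


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _flanked_sequence(match: MotifMatch, entries: dict[str, Structure],
                      lengths: list[int], flank: int) -> str:
    entry = entries[match.entry_id]
    parts = []
    for (cid, start), length in zip(match.placements, lengths):
        chain = entry.chain(cid)
        sids = [r.seq_id for r in chain.residues]
        i0 = sids.index(start)
        lo = max(0, i0 - flank)
        hi = min(len(sids), i0 + length + flank)
        parts.append(chain.sequence[lo:hi])
    return "".join(parts)


def redundancy_filter(matches: list[MotifMatch],
                      db: SearchDatabase | list[Structure],
                      identity: float = 0.5, flank: int = 15
                      ) -> list[MotifMatch]:
    """Greedy sequence-redundancy filter over the matching regions.

    Matches are visited by ascending RMSD; one is kept iff its flanked
    sequence (matched fragments ± ``flank`` residues on each side) shares
    less than ``identity`` with every already-kept match. Idempotent and
    deterministic.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    entries = {s.id: s for s in
               (db.entries if isinstance(db, SearchDatabase) else db)}
    kept: list[MotifMatch] = []
    kept_seqs: list[str] = []
    for m in sorted(matches, key=MotifMatch.sort_key):
        lengths = [len(s) for s in m.sequences]
        seq = _flanked_sequence(m, entries, lengths, flank)
        if all(sequence_identity(seq, ks) < identity for ks in kept_seqs):
            kept.append(m)
            kept_seqs.append(seq)
    return kept


@dataclasses.dataclass
class DivergenceCurve:
    """Number of matches at or below each RMSD value (Fig.-style cumulative)."""

    rmsds: np.ndarray   # sorted ascending
    counts: np.ndarray  # cumulative count at each rmsd

    def count_below(self, cutoff: float) -> int:
        return int(np.searchsorted(self.rmsds, cutoff, side="right"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"rmsd": self.rmsds, "cumulative": self.counts})


def divergence_curve(matches: list[MotifMatch], top_k: int | None = None
                     ) -> DivergenceCurve:
    rmsds = np.sort(np.array([m.rmsd for m in matches]))
    if top_k is not None:
        rmsds = rmsds[:top_k]
    return DivergenceCurve(rmsds, np.arange(1, len(rmsds) + 1))


@dataclasses.dataclass
class LogoCounts:
    """Per query position × amino-acid counts over retained matches."""

    counts: pd.DataFrame  # index: 1-based position, columns: 20 amino acids

    @property
    def n_matches(self) -> int:
        return int(self.counts.iloc[0].sum()) if len(self.counts) else 0

    def dominant(self, position: int) -> str:
        return str(self.counts.loc[position].idxmax())


def logo_counts(matches: list[MotifMatch], top_k: int | None = None
                ) -> LogoCounts:
    """Count amino acids per query position over the best ``top_k`` matches."""
    use = sorted(matches, key=MotifMatch.sort_key)
    if top_k is not None:
        use = use[:top_k]
    if not use:
        return LogoCounts(pd.DataFrame(columns=list(AA20)))
    n_pos = sum(len(s) for s in use[0].sequences)
    mat = np.zeros((n_pos, len(AA20)), dtype=int)
    aa_index = {aa: j for j, aa in enumerate(AA20)}
    for m in use:
        seq = "".join(m.sequences)
        if len(seq) != n_pos:
            raise ValueError("matches have inconsistent segment lengths")
        for i, aa in enumerate(seq):
            if aa in aa_index:
                mat[i, aa_index[aa]] += 1
    df = pd.DataFrame(mat, index=np.arange(1, n_pos + 1), columns=list(AA20))
    return LogoCounts(df)
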