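"""CAMTA domain-architecture annotation.

CG-1 / TIG / ankyrin / IQ hits are ingested from hmmscan per-domain tabular
output (``--domtblout``); the calmodulin-binding domain (CaMBD) and the
bipartite nuclear localization signal are located by degenerate consensus
matching, and the CaMBD amphipathic helix is quantified by its Eisenberg
hydrophobic moment on an 18-residue helical wheel (100 deg per residue).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources

from .physchem import ProteinRecord

DOMAIN_NAMES = ("CG-1", "TIG", "ANK", "IQ", "CaMBD", "NLS")

# 22-position degenerate consensus of the CAMTA calmodulin-binding domain;
# bracketed positions admit either residue.
CAMBD_CONSENSUS = "WSVG[IV]LEK[VA][IV]LRWRRK[GR][SK]GLRG"

# Functional CaM-binding motif: W-X-V-X(2)-L-X-K-X(2)-[LF]-R-W-R-X-[KR]-X(3)-[FL]-R-X
FUNCTIONAL_CAM_MOTIF = re.compile(r"(?=(W.V.{2}L.K.{2}[LF]RWR.[KR].{3}[FL]R.))")

# Conventional IQ calmodulin-interaction motif.
IQ_MOTIF = re.compile(r"(?=([FILV]Q.{3}[RK]G.{3}[RK].{2}[FILVWY]))")


@dataclass
class DomainAnnotation:
    protein_id: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    evidence: str  # "hmm" or "consensus"
    score: float | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_name}: bad coordinates "
                f"{self.start}-{self.end}"
            )


@dataclass
class HelixProjection:
    """One 18-residue helical-wheel window and its hydrophobic moment."""

    window_start: int
    window: str
    hydrophobic_moment: float
    hydrophobic_face: list[int] = field(default_factory=list)

    def __post_init__(self):
        assert len(self.window) == 18
        assert self.hydrophobic_moment >= 0


def _load_scale() -> dict[str, float]:
    with resources.files("camtakit.data").joinpath("eisenberg_scale.json").open() as fh:
        return json.load(fh)["scale"]


EISENBERG = _load_scale()


def parse_consensus(consensus: str) -> list[set[str]]:
    """Expand a bracketed consensus string into per-position allowed sets."""
    positions: list[set[str]] = []
    i = 0
    while i < len(consensus):
        c = consensus[i]
        if c == "[":
            j = consensus.index("]", i)
            positions.append(set(consensus[i + 1 : j]))
            i = j + 1
        else:
            positions.append({c})
            i += 1
    return positions


def read_domtblout(path) -> list[DomainAnnotation]:
    """Parse hmmscan --domtblout into domain annotations.

    Uses the alignment-coordinate columns (ali from/to, fields 18-19) on the
    query protein; the profile name (field 1) becomes the domain name and the
    per-domain bit score (field 14) is retained.  Comment lines are skipped.
    Output is sorted by (protein, start).
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace-delimited "
                    f"domtblout fields, got {len(fields)}"
                )
            try:
                ann = DomainAnnotation(
                    protein_id=fields[3],
                    domain_name=fields[0],
                    start=int(fields[17]),
                    end=int(fields[18]),
                    evidence="hmm",
                    score=float(fields[13]),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed domtblout line: {exc}")
            annotations.append(ann)
    annotations.sort(key=lambda a: (a.protein_id, a.start))
    return annotations


def _consensus_hits(
    p: ProteinRecord, positions: list[set[str]], max_mismatch: int, name: str
) -> list[DomainAnnotation]:
    k = len(positions)
    hits = []
    for start in range(len(p.sequence) - k + 1):
        window = p.sequence[start : start + k]
        mism = sum(1 for aa, allowed in zip(window, positions) if aa not in allowed)
        if mism <= max_mismatch:
            hits.append(
                DomainAnnotation(p.id, name, start + 1, start + k, "consensus", float(mism))
            )
    return hits


def find_cambd(p: ProteinRecord, max_mismatch: int = 2) -> list[DomainAnnotation]:
    """Windows matching the 22-position CaMBD consensus with at most
    ``max_mismatch`` mismatches; the score field carries the mismatch count.
    Overlapping hits are allowed."""
    return _consensus_hits(p, parse_consensus(CAMBD_CONSENSUS), max_mismatch, "CaMBD")


def find_functional_cam_motif(p: ProteinRecord) -> list[DomainAnnotation]:
    """Exact matches of the functional CaM-binding motif (overlaps allowed)."""
    hits = []
    for m in FUNCTIONAL_CAM_MOTIF.finditer(p.sequence):
        s = m.start(1)
        hits.append(DomainAnnotation(p.id, "CaMBD", s + 1, s + len(m.group(1)), "consensus"))
    return hits


def find_iq(p: ProteinRecord) -> list[DomainAnnotation]:
    """Matches of the conventional IQ motif pattern (overlaps allowed)."""
    hits = []
    for m in IQ_MOTIF.finditer(p.sequence):
        s = m.start(1)
        hits.append(DomainAnnotation(p.id, "IQ", s + 1, s + len(m.group(1)), "consensus"))
    return hits


def find_bipartite_nls(p: ProteinRecord) -> list[DomainAnnotation]:
    """Classical bipartite NLS rule: two adjacent K/R, a spacer of 10-12
    arbitrary residues, then at least 3 K/R within the next 5 positions.

    This is a stand-in for server-based NLS prediction and is flagged as a
    consensus call in the output.  One hit is reported per start position
    (the shortest qualifying spacer).
    """
    seq = p.sequence
    basic = set("KR")
    hits = []
    for s in range(len(seq) - 1):
        if seq[s] not in basic or seq[s + 1] not in basic:
            continue
        for spacer in (10, 11, 12):
            tail_start = s + 2 + spacer
            tail = seq[tail_start : tail_start + 5]
            if len(tail) < 5:
                continue
            if sum(1 for aa in tail if aa in basic) >= 3:
                hits.append(
                    DomainAnnotation(p.id, "NLS", s + 1, tail_start + 5, "consensus")
                )
                break
    return hits


def hydrophobic_moment(
    window: str, angle_deg: float = 100.0, window_start: int = 1
) -> HelixProjection:
    """Hydrophobic moment of an 18-residue window on a helical wheel.

    mu_H is the magnitude of the vector sum of per-residue Eisenberg
    hydrophobicities placed at successive ``angle_deg`` rotations.  The
    hydrophobic face is the set of residue positions (1-based within the
    window) whose wheel angle lies within +/-90 deg of the resultant vector;
    it is empty when the moment vanishes.
    """
    if len(window) != 18:
        raise ValueError(f"helical-wheel window must be 18 residues, got {len(window)}")
    delta = math.radians(angle_deg)
    x = sum(EISENBERG[aa] * math.cos(n * delta) for n, aa in enumerate(window))
    y = sum(EISENBERG[aa] * math.sin(n * delta) for n, aa in enumerate(window))
    moment = math.hypot(x, y)
    face: list[int] = []
    if moment > 1e-9:
        direction = math.atan2(y, x)
        for n in range(18):
            diff = (n * delta - direction + math.pi) % (2 * math.pi) - math.pi
            if abs(diff) <= math.pi / 2:
                face.append(n + 1)
    return HelixProjection(window_start, window, moment, face)


def best_amphipathic_window(p: ProteinRecord, angle_deg: float = 100.0) -> HelixProjection:
    """The 18-residue window of maximal hydrophobic moment (first on ties)."""
    if len(p.sequence) < 18:
        raise ValueError(f"{p.id}: shorter than one 18-residue window")
    best = None
    for s in range(len(p.sequence) - 17):
        proj = hydrophobic_moment(p.sequence[s : s + 18], angle_deg, window_start=s + 1)
        if best is None or proj.hydrophobic_moment > best.hydrophobic_moment:
            best = proj
    return best


_CANONICAL_SET = frozenset({"CG-1", "TIG", "ANK", "IQ", "CaMBD"})


def classify_architecture(
    domains: list[DomainAnnotation], protein_id: str
) -> tuple[str, list[str]]:
    """Classify one protein's domain complement.

    canonical: all of CG-1, TIG, ANK, IQ, CaMBD present.  non-TIG: all but
    TIG (the family's known variant architecture).  Otherwise incomplete,
    with the sorted missing list returned.
    """
    present = {d.domain_name for d in domains if d.protein_id == protein_id}
    missing = sorted(_CANONICAL_SET - present)
    if not missing:
        return "canonical", []
    if missing == ["TIG"]:
        return "non-TIG", ["TIG"]
    return "incomplete", missing
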