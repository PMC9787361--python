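"""Sliding-window nucleotide diversity (π) and polymorphism hotspot calling.

π is the average proportion of differing sites between two sequences
drawn from the alignment: π = Σ_{i<j} d_ij / (C(n,2) · L_eff), where
d_ij counts differing effective sites and L_eff is the number of
effective sites.  No multiple-hit correction is applied — at plastome
divergence levels the raw proportion is the quantity reported by the
standard sliding-window tools this module mirrors.

Two gap policies are supported: ``exclude-columns`` (any column holding a
gap or N is removed before counting — the "complete deletion" analogue)
and ``pairwise-delete`` (each pair skips only its own gapped sites).

A highly polymorphic region (HPR) is a maximal run of qualifying windows
under a calling rule (z-score, absolute threshold, or top-n).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .plastome_io import RegionMap

__all__ = [
    "WindowSpec",
    "DiversityProfile",
    "HPRCall",
    "nucleotide_diversity",
    "sliding_pi",
    "call_hprs",
    "assign_region",
    "shared_hprs",
    "region_shares",
    "read_fasta_alignment",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in alignment columns."""

    window_length: int = 600
    step: int = 200
    gap_policy: str = "exclude-columns"  # or "pairwise-delete"

    def __post_init__(self):
        if not (0 < self.step <= self.window_length):
            raise ValueError("require 0 < step <= window_length")
        if self.gap_policy not in ("exclude-columns", "pairwise-delete"):
            raise ValueError(f"unknown gap policy {self.gap_policy!r}")


@dataclass(frozen=True)
class HPRCall:
    """One called hotspot: a maximal interval of qualifying windows."""

    start: int
    end: int
    peak_pi: float
    mean_pi: float
    loci: tuple[str, ...] = ()
    region: str | None = None


class DiversityProfile:
    """Per-window π values over an alignment."""

    def __init__(self, rows: list[tuple[int, int, int, float]]):
        # rows: (start, end, n_effective_sites, pi); pi may be nan
        self.df = pd.DataFrame(rows, columns=["start", "end", "n_effective_sites", "pi"])
        self.df["midpoint"] = (self.df["start"] + self.df["end"]) // 2

    def __len__(self):
        return len(self.df)


def read_fasta_alignment(path) -> tuple[list[str], list[str]]:
    """(names, rows) from an aligned FASTA file."""
    names, rows, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                names.append(line[1:].split()[0])
            elif line:
                cur.append(line.upper())
    if cur:
        rows.append("".join(cur))
    if len(set(map(len, rows))) > 1:
        raise ValueError("aligned FASTA rows differ in length")
    return names, rows


def _encode(rows: list[str]) -> np.ndarray:
    """n × L integer matrix; gaps/N/ambiguity become -1."""
    n, length = len(rows), len(rows[0])
    mat = np.full((n, length), -1, dtype=np.int8)
    lut = np.full(256, -1, dtype=np.int8)
    for base, code in _CODE.items():
        lut[ord(base)] = code
        lut[ord(base.lower())] = code
    for i, row in enumerate(rows):
        mat[i] = lut[np.frombuffer(row.encode(), dtype=np.uint8)]
    return mat


def _pi_from_matrix(mat: np.ndarray, gap_policy: str) -> tuple[float, int]:
    """(pi, n_effective_sites); pi is nan when undefined."""
    n = mat.shape[0]
    npairs = n * (n - 1) // 2
    if gap_policy == "exclude-columns":
        keep = ~(mat < 0).any(axis=0)
        eff = int(keep.sum())
        if eff == 0:
            return float("nan"), 0
        sub = mat[:, keep]
        # per-column pairwise differences from base counts
        counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
        same = (counts * (counts - 1) // 2).sum(axis=0)
        diffs = int((npairs - same).sum())
        return diffs / (npairs * eff), eff
    # pairwise deletion: per pair, its own effective sites
    total = 0.0
    eff_union = int((~(mat < 0).all(axis=0)).sum())
    for i, j in combinations(range(n), 2):
        ok = (mat[i] >= 0) & (mat[j] >= 0)
        l_ij = int(ok.sum())
        if l_ij == 0:
            continue
        total += float((mat[i, ok] != mat[j, ok]).sum()) / l_ij
    return total / npairs, eff_union


def nucleotide_diversity(rows: list[str], gap_policy: str = "exclude-columns") -> float:
    """π of a whole alignment (list of equal-length gapped sequences)."""
    if len(rows) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    if len(set(map(len, rows))) > 1:
        raise ValueError("sequences must be aligned to equal length")
    pi, _eff = _pi_from_matrix(_encode(rows), gap_policy)
    return pi


def sliding_pi(rows: list[str], spec: WindowSpec | None = None) -> DiversityProfile:
    """Per-window π; the trailing partial window is dropped."""
    spec = spec or WindowSpec()
    if len(rows) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    length = len(rows[0])
    if length < spec.window_length:
        raise ValueError("alignment shorter than one window")
    mat = _encode(rows)
    out = []
    for start in range(0, length - spec.window_length + 1, spec.step):
        end = start + spec.window_length
        pi, eff = _pi_from_matrix(mat[:, start:end], spec.gap_policy)
        out.append((start, end, eff, pi))
    return DiversityProfile(out)


def _qualifying(profile: DiversityProfile, rule: str) -> np.ndarray:
    pi = profile.df["pi"].to_numpy()
    finite = np.isfinite(pi)
    kind, _, arg = rule.partition(":")
    if kind == "zscore":
        k = float(arg or 2.0)
        vals = pi[finite]
        if len(vals) == 0:
            return np.zeros(len(pi), dtype=bool)
        sd = float(np.std(vals))
        if sd == 0.0:
            return np.zeros(len(pi), dtype=bool)
        thresh = float(np.mean(vals)) + k * sd
        return finite & (pi > thresh)
    if kind == "absolute":
        return finite & (pi > float(arg))
    if kind == "top-n":
        n = int(arg)
        mask = np.zeros(len(pi), dtype=bool)
        order = np.argsort(np.where(finite, pi, -np.inf))[::-1]
        mask[order[:n]] = True
        return mask & finite
    raise ValueError(f"unknown HPR rule {rule!r}")


def call_hprs(profile: DiversityProfile, rule: str = "zscore:2",
              loci: list[tuple[str, int, int]] | None = None) -> list[HPRCall]:
    """Merge qualifying windows into maximal hotspot intervals.

    ``rule`` is ``zscore:k``, ``absolute:t`` or ``top-n:n``.  Overlapping
    or adjacent qualifying windows coalesce into one call; optional locus
    annotations (label, start, end in alignment columns) attach every
    overlapping label to the call.
    """
    mask = _qualifying(profile, rule)
    df = profile.df
    calls: list[HPRCall] = []
    run: list[int] = []
    order = np.argsort(df["start"].to_numpy())

    def flush(indices: list[int]):
        if not indices:
            return
        start = int(df["start"].iloc[indices].min())
        end = int(df["end"].iloc[indices].max())
        vals = df["pi"].iloc[indices]
        labels = tuple(lab for lab, s, e in (loci or []) if s < end and e > start)
        calls.append(HPRCall(start=start, end=end, peak_pi=float(vals.max()),
                             mean_pi=float(vals.mean()), loci=labels))

    prev_end = None
    for idx in order:
        if not mask[idx]:
            continue
        s = int(df["start"].iloc[idx])
        if run and prev_end is not None and s > prev_end:
            flush(run)
            run = []
        run.append(int(idx))
        e = int(df["end"].iloc[idx])
        prev_end = e if prev_end is None or e > prev_end else prev_end
    flush(run)
    return calls


def assign_region(hpr: HPRCall, column_map, regions: RegionMap) -> str | None:
    """Region label (LSC/SSC/IR) by majority-bp overlap of the mapped interval.

    ``column_map`` maps an alignment column to a genome coordinate (or
    None for unmappable columns) and must be monotone over the mappable
    columns.
    """
    votes = {"LSC": 0, "SSC": 0, "IR": 0}
    mapped = 0
    for col in range(hpr.start, hpr.end):
        pos = column_map(col)
        if pos is None:
            continue
        mapped += 1
        region = regions.region_of(pos)
        votes["IR" if region in ("IRa", "IRb") else region] += 1
    if mapped == 0:
        return None
    return max(votes, key=lambda k: (votes[k], k))


def region_shares(calls: list[HPRCall]) -> dict[str, float]:
    """Percentage of calls per region label (None-labelled calls excluded)."""
    labelled = [c.region for c in calls if c.region is not None]
    if not labelled:
        return {}
    return {region: 100.0 * labelled.count(region) / len(labelled)
            for region in sorted(set(labelled))}


def shared_hprs(calls_by_group: dict[str, list[HPRCall]]) -> pd.DataFrame:
    """Loci called in two or more groups, matched by locus label."""
    bearers: dict[str, set[str]] = {}
    for group, calls in calls_by_group.items():
        for call in calls:
            for locus in call.loci:
                bearers.setdefault(locus, set()).add(group)
    rows = [{"locus": locus, "n_groups": len(groups),
             "groups": ",".join(sorted(groups))}
            for locus, groups in sorted(bearers.items()) if len(groups) >= 2]
    return pd.DataFrame(rows, columns=["locus", "n_groups", "groups"])
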