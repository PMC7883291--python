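"""Assign cross-links to chain pairs, extract Cα–Cα distances, and classify
against the linker-imposed distance cutoff.

In a homo-oligomer, one residue-pair cross-link maps onto many chain-pair
combinations (both endpoints intra one chain, or split across any two
chains).  Following the shortest-combination rule, the minimal distance over
all combinations represents the link: taking the minimum over *all* chain
pairs subsumes any "neighboring subunit" definition, because the minimum
over all pairs equals the minimum over neighbors for ring geometries.

A link whose shortest combination exceeds the active threshold (default
30 Å, the maximal Cα–Cα bridge of DSS/DSSO-class lysine cross-linkers) is
flagged over-length.  Replicate filtering keeps a link only if it was
observed in at least ``min_replicates`` distinct replicates (default 2 of
3), summing spectral counts over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import CrossLink, CrossLinkTable, StructureModel


class MappingError(Exception):
    pass


class ConfigError(Exception):
    pass


class SummaryError(Exception):
    pass


@dataclass
class AnalysisConfig:
    """Knobs of the mapping stage.

    ``distance_threshold`` (Å) separates satisfied from over-length links;
    ``histogram_bin_width`` (Å) sets the half-open distance bins;
    ``min_replicates`` is the replicate-evidence filter;
    ``inter_chain_policy`` is ``all_pairs`` (enumerate every chain-pair
    combination) or ``same_chain_only`` (intra-chain distances only).
    """

    distance_threshold: float = 30.0
    histogram_bin_width: float = 5.0
    min_replicates: int = 2
    inter_chain_policy: str = "all_pairs"

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ConfigError("distance_threshold must be > 0")
        if self.histogram_bin_width <= 0:
            raise ConfigError("histogram_bin_width must be > 0")
        if self.inter_chain_policy not in ("all_pairs", "same_chain_only"):
            raise ConfigError(
                f"unknown inter_chain_policy {self.inter_chain_policy!r}"
            )


@dataclass
class MappedLink:
    """A cross-link resolved onto chain pairs of one structure.

    ``assignments`` holds every enumerated (chain_a, chain_b, distance)
    combination sorted ascending by distance; ``shortest`` is the first.
    For an inter-chain pair the distance is the smaller of the two residue
    placements (endpoint a on chain 1 / b on chain 2, and vice versa).
    """

    link: CrossLink
    assignments: list[tuple[str, str, float]]
    overlength: bool = False
    unmapped_reason: str | None = None

    @property
    def shortest(self) -> tuple[str, str, float] | None:
        return self.assignments[0] if self.assignments else None

    @property
    def distance(self) -> float | None:
        return self.assignments[0][2] if self.assignments else None

    @property
    def is_mapped(self) -> bool:
        return bool(self.assignments)

    @property
    def is_self(self) -> bool:
        return self.link.is_self


def _resolve(structure: StructureModel, chain_id: str, pos: int,
             offsets: dict[str, int] | None) -> np.ndarray | None:
    off = 0 if offsets is None else offsets.get(chain_id, 0)
    return structure.chains[chain_id].ca(pos + off)


def enumerate_assignments(
    link: CrossLink,
    structure: StructureModel,
    config: AnalysisConfig | None = None,
    offsets: dict[str, int] | None = None,
) -> tuple[list[tuple[str, str, float]], str | None]:
    """Enumerate every chain-pair combination of a link with its distance.

    Returns the ascending-sorted assignment list and, when it is empty, a
    reason ('missing Cα', ...).  A protein absent from the structure's
    chain map raises :class:`MappingError`.
    """
    config = config or AnalysisConfig()
    link = link.canonical()
    chains_a = structure.chains_for(link.protein_a)
    chains_b = structure.chains_for(link.protein_b)
    if not chains_a:
        raise MappingError(f"protein {link.protein_a!r} absent from structure")
    if not chains_b:
        raise MappingError(f"protein {link.protein_b!r} absent from structure")

    out: list[tuple[str, str, float]] = []
    seen_pairs: set[tuple[str, str]] = set()
    any_residue_found = False
    for ca_id in chains_a:
        xa = _resolve(structure, ca_id, link.pos_a, offsets)
        for cb_id in chains_b:
            pair = tuple(sorted((ca_id, cb_id)))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            if config.inter_chain_policy == "same_chain_only" and ca_id != cb_id:
                continue
            xb = _resolve(structure, cb_id, link.pos_b, offsets)
            if ca_id == cb_id:
                if link.pos_a == link.pos_b:
                    continue  # same residue on the same chain: degenerate
                if xa is None or xb is None:
                    continue
                any_residue_found = True
                out.append((ca_id, cb_id, float(np.linalg.norm(xa - xb))))
            else:
                # two placements across the chain pair; keep the smaller
                xa2 = _resolve(structure, cb_id, link.pos_a, offsets)
                xb2 = _resolve(structure, ca_id, link.pos_b, offsets)
                cands = []
                if xa is not None and xb is not None:
                    cands.append(np.linalg.norm(xa - xb))
                if xa2 is not None and xb2 is not None:
                    cands.append(np.linalg.norm(xa2 - xb2))
                if cands:
                    any_residue_found = True
                    out.append((pair[0], pair[1], float(min(cands))))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    if not out:
        reason = "missing Cα" if not any_residue_found else "no valid combination"
        return [], reason
    return out, None


def map_table(
    table: CrossLinkTable,
    structure: StructureModel,
    config: AnalysisConfig | None = None,
    offsets: dict[str, int] | None = None,
) -> list[MappedLink]:
    """Map every unique link of a table onto a structure.

    One :class:`MappedLink` per canonical residue pair (CSM counts summed
    over duplicate rows); the shortest combination carries the over-length
    flag.  Unmapped links are kept with their reason, never dropped.
    """
    if len(table) == 0:
        raise MappingError("cannot map an empty cross-link table")
    config = config or AnalysisConfig()

    merged: dict[tuple, CrossLink] = {}
    for ln in table.links:
        key = ln.key
        if key in merged:
            prev = merged[key]
            merged[key] = CrossLink(
                protein_a=prev.protein_a, pos_a=prev.pos_a,
                protein_b=prev.protein_b, pos_b=prev.pos_b,
                csm_count=prev.csm_count + ln.csm_count,
                replicate=prev.replicate, condition=prev.condition,
            )
        else:
            merged[key] = ln.canonical()

    mapped: list[MappedLink] = []
    for key in sorted(merged):
        ln = merged[key]
        try:
            assignments, reason = enumerate_assignments(
                ln, structure, config, offsets)
        except MappingError as exc:
            mapped.append(MappedLink(link=ln, assignments=[],
                                     unmapped_reason=str(exc)))
            continue
        over = bool(assignments) and assignments[0][2] > config.distance_threshold
        mapped.append(MappedLink(link=ln, assignments=assignments,
                                 overlength=over, unmapped_reason=reason))
    return mapped


def deduplicate_and_filter(
    table: CrossLinkTable,
    config: AnalysisConfig | None = None,
) -> CrossLinkTable:
    """Apply the replicate-evidence filter to a cross-link table.

    A unique link (canonical residue pair) is kept iff it was observed in at
    least ``min_replicates`` distinct replicates.  The output stays
    replicate-resolved (one row per observation, exact duplicates already
    collapsed), which makes the filter idempotent; spectral counts are
    summed over replicates wherever unique links are consumed
    (:func:`map_table`, exports).
    """
    config = config or AnalysisConfig()
    n_reps_present = len(table.replicates()) if len(table) else 0
    if config.min_replicates > 1 and n_reps_present and \
            config.min_replicates > n_reps_present:
        raise ConfigError(
            f"min_replicates={config.min_replicates} exceeds the "
            f"{n_reps_present} replicate(s) present in the table"
        )

    by_key: dict[tuple, list[CrossLink]] = {}
    for ln in table.links:
        by_key.setdefault(ln.key, []).append(ln)

    kept: list[CrossLink] = []
    for key in sorted(by_key):
        group = by_key[key]
        if len({l.replicate for l in group}) < config.min_replicates:
            continue
        kept.extend(sorted(group, key=lambda l: (l.replicate, l.csm_count)))
    return CrossLinkTable(links=kept,
                          provenance=f"{table.provenance}|filtered>={config.min_replicates}")


@dataclass
class DistanceSummary:
    histogram: dict[float, int]      # bin left edge -> count (half-open bins)
    bin_width: float
    n_unique: int
    n_overlength: int
    n_self: int
    n_unmapped: int
    mean_distance: float
    unmapped_reasons: dict[str, int] = field(default_factory=dict)


def distance_summary(
    mapped: list[MappedLink],
    config: AnalysisConfig | None = None,
) -> DistanceSummary:
    """Histogram and summary statistics over shortest-combination distances.

    Bins are half-open ``[k*w, (k+1)*w)``.  Self-links (a residue to itself)
    and unmapped links are excluded from the histogram and the mean but
    reported as separate counts.
    """
    config = config or AnalysisConfig()
    if not mapped:
        raise SummaryError("no mapped links to summarize")
    usable = [m for m in mapped if m.is_mapped and not m.is_self]
    unmapped = [m for m in mapped if not m.is_mapped]
    n_self = sum(1 for m in mapped if m.is_self and m.is_mapped)
    if not usable:
        raise SummaryError("all links unmapped or self-links; nothing to summarize")

    dists = np.array([m.distance for m in usable])
    w = config.histogram_bin_width
    bins = np.floor(dists / w).astype(int)
    hist = {float(b * w): int(n) for b, n in
            zip(*np.unique(bins, return_counts=True))}
    reasons: dict[str, int] = {}
    for m in unmapped:
        reasons[m.unmapped_reason or "unknown"] = \
            reasons.get(m.unmapped_reason or "unknown", 0) + 1
    return DistanceSummary(
        histogram=hist,
        bin_width=w,
        n_unique=len(usable),
        n_overlength=int(np.sum(dists > config.distance_threshold)),
        n_self=n_self,
        n_unmapped=len(unmapped),
        mean_distance=float(np.mean(dists)),
        unmapped_reasons=reasons,
    )


@dataclass
class OverlapStats:
    n_a: int
    n_b: int
    n_intersection: int
    n_only_a: int
    n_only_b: int
    pct_of_a: float | None   # |A∩B| / |A| * 100; None when A is empty
    pct_of_b: float | None
    three_way: dict[str, int] | None = None


def overlap_stats(set_a: set, set_b: set, set_c: set | None = None) -> OverlapStats:
    """Intersection counts and directional percentages of unique-link sets.

    The percentage is directional: ``pct_of_a`` is the share of A's links
    also present in B (the convention used when quoting "x% of in-gel links
    were also detected in solution").  Empty sets give zero counts and a
    ``None`` percentage.
    """
    set_a, set_b = set(set_a), set(set_b)
    inter = set_a & set_b
    stats = OverlapStats(
        n_a=len(set_a), n_b=len(set_b),
        n_intersection=len(inter),
        n_only_a=len(set_a - set_b),
        n_only_b=len(set_b - set_a),
        pct_of_a=100.0 * len(inter) / len(set_a) if set_a else None,
        pct_of_b=100.0 * len(inter) / len(set_b) if set_b else None,
    )
    if set_c is not None:
        set_c = set(set_c)
        stats.three_way = {
            "abc": len(set_a & set_b & set_c),
            "ab_only": len((set_a & set_b) - set_c),
            "ac_only": len((set_a & set_c) - set_b),
            "bc_only": len((set_b & set_c) - set_a),
            "a_only": len(set_a - set_b - set_c),
            "b_only": len(set_b - set_a - set_c),
            "c_only": len(set_c - set_a - set_b),
        }
    return stats
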