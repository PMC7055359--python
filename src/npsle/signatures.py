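"""Gene-set overlap and enrichment statistics over a common background.

Cross-model signatures are exact set intersections of differentially
expressed gene sets restricted to a shared ("common") background universe.
Overlap significance uses the exact hypergeometric distribution evaluated in
log-space; enrichment is the observed overlap divided by the chance
expectation K*n/N, so 1 marks chance level.

Gene identifiers are compared case-insensitively (mouse symbols are written
with mixed capitalization, e.g. ApoE/Apoe) while the first-seen spelling is
preserved for output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "OverlapResult",
    "normalize_ids",
    "common_background",
    "hypergeom_tail",
    "compute_overlap",
    "intersect_signature",
    "enrichment_panel",
    "random_set_enrichment",
    "assemble_dam_signature",
]


def normalize_ids(ids) -> dict[str, str]:
    """Case-insensitive deduplication: canonical (lower) id -> first-seen spelling."""
    out: dict[str, str] = {}
    dropped = 0
    for raw in ids:
        key = str(raw).strip().lower()
        if not key:
            continue
        if key in out:
            dropped += 1
        else:
            out[key] = str(raw).strip()
    if dropped:
        logger.warning("dropped %d duplicate identifiers (case-insensitive)", dropped)
    return out


@dataclass
class GeneSet:
    """A named gene set over a background universe.

    Members and background are stored case-normalized; ``display`` maps the
    normalized id back to its original spelling. Members must be contained in
    the background.
    """

    name: str
    members: frozenset
    background: frozenset
    display: dict = field(default_factory=dict)

    @classmethod
    def from_lists(cls, name: str, members, background) -> "GeneSet":
        mem = normalize_ids(members)
        bg = normalize_ids(background)
        display = {**bg, **mem}
        outside = set(mem) - set(bg)
        if outside:
            logger.warning(
                "gene set %r: %d members outside the background dropped",
                name,
                len(outside),
            )
        return cls(
            name=name,
            members=frozenset(set(mem) - outside),
            background=frozenset(bg),
            display=display,
        )

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background must be non-empty")
        if not self.members <= self.background:
            raise ValueError("members must be a subset of the background")

    def __len__(self) -> int:
        return len(self.members)

    def restricted(self, background: frozenset) -> "GeneSet":
        """Restrict members and background to the given universe."""
        bg = frozenset(background)
        dropped = len(self.members - bg)
        if dropped:
            logger.warning(
                "gene set %r: %d members outside the common background dropped",
                self.name,
                dropped,
            )
        return GeneSet(self.name, self.members & bg, self.background & bg, self.display)

    def member_names(self) -> list[str]:
        return sorted(self.display.get(m, m) for m in self.members)


@dataclass
class OverlapResult:
    """Hypergeometric overlap statistics for two sets over a background of size N.

    K and n are the set sizes, k the observed overlap; expected = K*n/N,
    enrichment = k/expected, and p_over/p_under are the exact upper
    P(X >= k) and lower P(X <= k) tail probabilities.
    """

    N: int
    K: int
    n: int
    k: int
    expected: float
    enrichment: float
    p_over: float
    p_under: float
    overlap_members: frozenset = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "expected": self.expected,
            "enrichment": self.enrichment,
            "p_over": self.p_over,
            "p_under": self.p_under,
        }


def common_background(universe_a, universe_b) -> frozenset:
    """Exact intersection of two gene universes (case-normalized)."""
    a = frozenset(normalize_ids(universe_a))
    b = frozenset(normalize_ids(universe_b))
    if not a or not b:
        raise ValueError("both universes must be non-empty")
    common = a & b
    if not common:
        raise ValueError(
            f"universes share no genes (|A|={len(a)}, |B|={len(b)}); "
            "check identifier conventions"
        )
    return common


def _log_pmf(x: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    # log C(K,x) + log C(N-K, n-x) - log C(N,n) via log-gamma
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(K, x) + logC(N - K, n - x) - logC(N, n)


def hypergeom_tail(N: int, K: int, n: int, k: int, tail: str = "over") -> float:
    """Exact hypergeometric tail probability.

    Population N, K marked items, n draws without replacement, observed
    overlap k. tail="over" gives P(X >= k); tail="under" gives P(X <= k).
    Evaluated by summing the pmf in log-space.
    """
    for name, v in (("N", N), ("K", K), ("n", n)):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"K and n must not exceed N (N={N}, K={K}, n={n})")
    lo, hi = max(0, K + n - N), min(K, n)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    if tail == "over":
        xs = np.arange(k, hi + 1)
    elif tail == "under":
        xs = np.arange(lo, k + 1)
    else:
        raise ValueError("tail must be 'over' or 'under'")
    return float(min(1.0, np.exp(logsumexp(_log_pmf(xs, N, K, n)))))


def compute_overlap(set_a: GeneSet, set_b: GeneSet, background=None) -> OverlapResult:
    """Overlap statistics for two gene sets over a shared background."""
    if background is None:
        if set_a.background != set_b.background:
            background = set_a.background & set_b.background
            if not background:
                raise ValueError("gene sets have disjoint backgrounds")
        else:
            background = set_a.background
    background = frozenset(background)
    a = set_a.restricted(background)
    b = set_b.restricted(background)
    N, K, n = len(background), len(a), len(b)
    overlap = a.members & b.members
    k = len(overlap)
    expected = K * n / N if N else 0.0
    return OverlapResult(
        N=N,
        K=K,
        n=n,
        k=k,
        expected=expected,
        enrichment=(k / expected) if expected > 0 else 0.0,
        p_over=hypergeom_tail(N, K, n, k, "over"),
        p_under=hypergeom_tail(N, K, n, k, "under"),
        overlap_members=frozenset(overlap),
    )


def intersect_signature(up_a: GeneSet, up_b: GeneSet) -> tuple[GeneSet, OverlapResult]:
    """Cross-model signature: exact intersection of two upregulated sets.

    Both sets are first restricted to the common background of their
    universes; the returned OverlapResult carries the upper-tail p.
    """
    background = common_background(up_a.background, up_b.background)
    result = compute_overlap(up_a, up_b, background)
    display = {**up_a.display, **up_b.display}
    sig = GeneSet(
        name=f"{up_a.name}&{up_b.name}",
        members=result.overlap_members,
        background=frozenset(background),
        display=display,
    )
    return sig, result


def enrichment_panel(
    up: GeneSet,
    down: GeneSet,
    ref_over: GeneSet,
    ref_under: GeneSet,
    background,
) -> dict[tuple[str, str], OverlapResult]:
    """2x2 enrichment panel of DE sets against reference over/under sets.

    Keys are (de_direction, reference_direction) with values the overlap of
    the up/down-regulated set against the reference over/under-expressed set
    on the shared background. Enrichment 1 marks chance level.
    """
    background = frozenset(normalize_ids(background))
    if up.members & down.members:
        raise ValueError("a gene cannot be both up- and down-regulated")
    panel = {}
    for de_name, de_set in (("up", up), ("down", down)):
        for ref_name, ref_set in (("over", ref_over), ("under", ref_under)):
            panel[(de_name, ref_name)] = compute_overlap(de_set, ref_set, background)
    return panel


def random_set_enrichment(
    background_size: int,
    reference_size: int,
    draw_size: int,
    n_draws: int,
    rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Enrichment ratios of uniformly random sets against a fixed reference.

    Draws ``n_draws`` uniform subsets of ``draw_size`` from a background of
    ``background_size`` identifiers containing a fixed reference set of
    ``reference_size``, and returns each draw's observed/expected enrichment.
    The mean converges to 1 (chance level) as draws grow — the dotted-line
    null of an enrichment panel.
    """
    N, K, n = background_size, reference_size, draw_size
    if not (0 < K <= N and 0 < n <= N):
        raise ValueError("need 0 < reference_size, draw_size <= background_size")
    ref_mask = np.zeros(N, dtype=bool)
    ref_mask[:K] = True
    expected = K * n / N
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        keys = rng.random((m, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        out[done : done + m] = ref_mask[idx].sum(axis=1) / expected
        done += m
    return out


def assemble_dam_signature(
    dam_genes: GeneSet, de_tables: dict[str, pd.DataFrame]
) -> tuple[GeneSet, pd.DataFrame]:
    """Assemble the combined disease-associated-microglia (DAM) signature.

    The signature is the union over models of (DAM reference genes that are
    differentially expressed in that model); each member is annotated with its
    regulation direction in every model where it is differential. DE tables
    are indexed by gene with boolean ``significant`` and ``direction``
    columns. DAM identifiers absent from every DE universe are logged, not
    fatal.
    """
    norm_tables = {}
    for model, table in de_tables.items():
        idx = {str(g).strip().lower(): g for g in table.index}
        norm_tables[model] = (table, idx)

    unresolved = [
        g
        for g in dam_genes.members
        if not any(g in idx for _, idx in norm_tables.values())
    ]
    if unresolved:
        logger.warning(
            "%d DAM genes unresolvable in any DE table: %s",
            len(unresolved),
            sorted(unresolved)[:10],
        )

    rows = []
    members = set()
    for g in sorted(dam_genes.members):
        row = {"gene": dam_genes.display.get(g, g)}
        differential = False
        for model, (table, idx) in norm_tables.items():
            direction = None
            if g in idx and bool(table.loc[idx[g], "significant"]):
                direction = str(table.loc[idx[g], "direction"])
                differential = True
            row[model] = direction
        if differential:
            members.add(g)
            rows.append(row)

    provenance = pd.DataFrame(rows, columns=["gene", *norm_tables])
    signature = GeneSet(
        name=f"{dam_genes.name}-signature",
        members=frozenset(members),
        background=dam_genes.background,
        display=dam_genes.display,
    )
    return signature, provenance
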