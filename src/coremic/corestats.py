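"""Core-microbiome statistics.

For each taxon, presence/absence across the interest in-group and the
out-group forms a 2x2 contingency table

    =============  ========  =======
                   present   absent
    =============  ========  =======
    in-group          a         b
    out-group         c         d
    =============  ========  =======

and the one-tailed Fisher's exact p-value is the upper hypergeometric tail

    p = P(X >= a),   X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b),

i.e. the probability, with all margins fixed, of the taxon being present in
at least ``a`` of the in-group samples.  The p-values of *all* merged taxa
are adjusted by the Benjamini-Hochberg step-up procedure, and a taxon is
called core when its q-value passes the significance level, its in-group
presence reaches the minimum fraction, its out-group presence does not exceed
the optional ceiling, and its taxonomy is informative (named below kingdom).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.special import gammaln, logsumexp

from .table import AbundanceTable, GroupMap, ValidationError
from . import tableops
from .tableops import Lineage, PresenceMatrix, canonicalize_lineage

__all__ = [
    "ContingencyCounts",
    "CoreResult",
    "contingency_for_taxon",
    "fisher_one_tailed_p",
    "bh_adjust",
    "presence_fraction",
    "is_informative",
    "identify_core",
]


@dataclass(frozen=True)
class ContingencyCounts:
    """Presence/absence tallies: a,b in-group present/absent; c,d out-group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n_in(self) -> int:
        return self.a + self.b

    @property
    def n_out(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class CoreResult:
    """Per-taxon outcome of the core test; every merged taxon gets one."""

    taxonomy: Lineage
    counts: ContingencyCounts
    p_value: float
    q_value: float
    presence_in_pct: float
    presence_out_pct: float
    informative: bool
    is_core: bool


def contingency_for_taxon(
    presence: PresenceMatrix, taxon: str, groups: GroupMap
) -> ContingencyCounts:
    """Tally the 2x2 presence table for one taxon over the two sample sets."""
    if taxon not in presence.data.index:
        raise ValidationError(f"taxon {taxon!r} not in presence matrix")
    if groups.n_in == 0 or groups.n_out == 0:
        raise ValidationError("both in-group and out-group must be non-empty")
    cols = set(presence.sample_ids)
    for s in (*groups.in_samples, *groups.out_samples):
        if s not in cols:
            raise ValidationError(f"sample {s!r} from mapping not in table")
    row = presence.data.loc[taxon]
    a = int(row[list(groups.in_samples)].sum())
    c = int(row[list(groups.out_samples)].sum())
    return ContingencyCounts(a=a, b=groups.n_in - a, c=c, d=groups.n_out - c)


def fisher_one_tailed_p(counts: ContingencyCounts) -> float:
    """One-tailed Fisher's exact p: greater presence in the in-group.

    Computed by direct summation of the hypergeometric upper tail in
    log-space, which is overflow-free for any table size.  A degenerate table
    with no presence anywhere (a + c == 0) gives p = 1.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    N, K, n = a + b + c + d, a + c, a + b
    if n == 0 and counts.n_out == 0:
        raise ValidationError("empty contingency table")
    if K == 0:
        return 1.0
    k_hi = min(n, K)
    k_lo = max(0, n - (N - K))
    if a <= k_lo:
        return 1.0
    k = np.arange(a, k_hi + 1)
    log_pmf = (
        _log_comb(K, k)
        + _log_comb(N - K, n - k)
        - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sort ascending, set q(i) = min_{j >= i} p(j) * m / j clipped at 1, and
    return in the original input order.  Ties share the identical q.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def presence_fraction(present_count: int, group_size: int) -> float:
    """Percentage of samples in a group where the taxon is present.

    Reported rounded half-up to one decimal, the convention used for
    presence tables (e.g. 30/31 -> 96.8, 28/31 -> 90.3).
    """
    if group_size <= 0:
        raise ValidationError("group_size must be positive")
    if not 0 <= present_count <= group_size:
        raise ValidationError("present_count must lie in [0, group_size]")
    pct = Decimal(100 * present_count) / Decimal(group_size)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def is_informative(lineage: Lineage, min_named_ranks: int = 2) -> bool:
    """Whether a lineage carries enough named ranks to be reportable.

    The default of 2 marks kingdom-only lineages like
    "k__Bacteria;p__;c__;o__;f__;g__;s__" uninformative while keeping taxa
    named only down to an intermediate rank (e.g. order "o__B97").
    """
    return lineage.named_ranks >= min_named_ranks


def identify_core(
    tables: list[AbundanceTable],
    groups: GroupMap,
    alpha: float = 0.05,
    min_in_pct: float = 90.0,
    max_out_pct: float = 100.0,
    detection_threshold: float = 1,
    normalization: str = "none",
    norm_depth: int | None = None,
    min_depth: float = 0,
    min_named_ranks: int = 2,
    seed: int | None = None,
) -> list[CoreResult]:
    """Run the full core-identification pipeline and score every taxon.

    Pipeline order is fixed: collapse each table by taxonomy -> intersection
    merge -> optional sample depth filter -> normalization -> binarization ->
    per-taxon Fisher p over ALL merged taxa -> Benjamini-Hochberg over that
    full p-vector -> q < alpha -> in-group presence >= min_in_pct ->
    out-group presence <= max_out_pct -> informativeness filter.  BH runs
    before the presence filters because filtering first would change the FDR
    family.  Presence thresholds compare unrounded fractions; rounding is
    display-only.

    Returns one :class:`CoreResult` per merged taxon (core or not), sorted by
    canonical taxonomy so the output is invariant to input row/sample order.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    collapsed = [tableops.collapse_by_taxonomy(t) for t in tables]
    merged = tableops.merge_tables(collapsed)
    if merged.n_rows == 0:  # pragma: no cover - merge_tables already errors
        raise ValidationError("zero taxa after merge")
    if min_depth > 0:
        merged = tableops.filter_low_depth_samples(merged, min_depth)
    merged = tableops.normalize(merged, normalization, depth=norm_depth, seed=seed)
    present = tableops.binarize(merged, detection_threshold)

    cols = set(present.sample_ids)
    dropped = [
        s for s in (*groups.in_samples, *groups.out_samples) if s not in cols
    ]
    if dropped:
        groups = groups.restrict(cols)
    if groups.n_in == 0 or groups.n_out == 0:
        raise ValidationError("a group lost all its samples during filtering")

    in_cols = list(groups.in_samples)
    out_cols = list(groups.out_samples)
    a_vec = present.data[in_cols].sum(axis=1).to_numpy(dtype=int)
    c_vec = present.data[out_cols].sum(axis=1).to_numpy(dtype=int)
    n_in, n_out = groups.n_in, groups.n_out

    taxa = present.row_ids
    tables_2x2 = [
        ContingencyCounts(a=int(a), b=n_in - int(a), c=int(c), d=n_out - int(c))
        for a, c in zip(a_vec, c_vec)
    ]
    p_vals = np.array([fisher_one_tailed_p(t) for t in tables_2x2])
    q_vals = bh_adjust(p_vals)

    results = []
    for taxon, cc, p, q in zip(taxa, tables_2x2, p_vals, q_vals):
        lineage = canonicalize_lineage(taxon)
        in_frac = 100.0 * cc.a / n_in
        out_frac = 100.0 * cc.c / n_out
        informative = is_informative(lineage, min_named_ranks)
        core = (
            q < alpha
            and in_frac >= min_in_pct
            and out_frac <= max_out_pct
            and informative
        )
        results.append(
            CoreResult(
                taxonomy=lineage,
                counts=cc,
                p_value=float(p),
                q_value=float(q),
                presence_in_pct=presence_fraction(cc.a, n_in),
                presence_out_pct=presence_fraction(cc.c, n_out),
                informative=informative,
                is_core=bool(core),
            )
        )
    results.sort(key=lambda r: r.taxonomy.canonical)
    return results
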