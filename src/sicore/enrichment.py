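"""Seed-sequence similarity and family over-representation of miRNA groups.

miRNA target binding is largely determined by the *seed*: the six bases at
positions 2-7 of the mature sequence.  If a detected co-regulation group is
driven by shared targeting, its members should carry unusually similar seeds
and be enriched for members of the same precursor family.  Two tests are
provided: a permutation test on the average pairwise edit distance of the
seeds within a group, and an upper-tail hypergeometric test on family
membership counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

RNA_ALPHABET = frozenset("ACGU")
SEED_START, SEED_END = 1, 7  # python slice for 1-based positions 2..7


@dataclass(frozen=True)
class SeedRecord:
    """A mature miRNA sequence with its derived seed."""

    mirna_id: str
    mature_sequence: str
    family: str | None = None

    @property
    def seed(self) -> str:
        return extract_seed(self.mature_sequence)


def extract_seed(mature_sequence: str) -> str:
    """The 6-mer between the 2nd and 7th bases of a mature miRNA.

    Sequences must be RNA over {A, C, G, U} and at least 7 bases long; DNA
    input (containing T) is converted to U with a warning, since public
    sequence files mix the two alphabets.
    """
    seq = mature_sequence.strip().upper()
    if "T" in seq:
        warnings.warn("sequence contains T; interpreting as DNA and converting to U",
                      stacklevel=2)
        seq = seq.replace("T", "U")
    if len(seq) < SEED_END:
        raise ValueError(f"mature sequence too short for a seed (need >= 7 bases): "
                         f"{mature_sequence!r}")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in sequence "
                         f"{mature_sequence!r}")
    return seq[SEED_START:SEED_END]


def edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance: unit-cost insertions, deletions, substitutions."""
    if not s1 or not s2:
        return max(len(s1), len(s2))
    return int(edlib.align(s1, s2, task="distance")["editDistance"])


def _seed_of(item) -> str:
    return item.seed if isinstance(item, SeedRecord) else str(item)


def group_similarity(group: Collection) -> float:
    """Average pairwise edit distance of the seeds in a group (>= 2 members)."""
    seeds = [_seed_of(x) for x in group]
    if len(seeds) < 2:
        raise ValueError("group similarity needs at least 2 members")
    dists = [edit_distance(seeds[i], seeds[j])
             for i in range(len(seeds)) for j in range(i + 1, len(seeds))]
    return float(np.mean(dists))


def permutation_test_similarity(groups: Mapping[str, Collection[str]],
                                universe: Sequence[SeedRecord],
                                n_perm: int = 10_000,
                                seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Permutation test of within-group seed similarity.

    For each group of size ``k``, ``n_perm`` uniform size-``k`` subsets of the
    universe are drawn and their average pairwise edit distance computed.
    The reported p-value is add-one smoothed,
    ``(1 + #draws with similarity <= observed) / (n_perm + 1)``, so finite
    permutations never yield p = 0.  The 95% null band (2.5% and 97.5%
    quantiles) and null median are reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [r.mirna_id for r in universe]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA ids in universe")
    index = {r.mirna_id: i for i, r in enumerate(universe)}
    seeds = [r.seed for r in universe]
    n = len(seeds)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = edit_distance(seeds[i], seeds[j])

    def mean_pairwise(idx: np.ndarray) -> float:
        sub = dist[np.ix_(idx, idx)]
        k = len(idx)
        return float(sub[np.triu_indices(k, 1)].mean()) if k > 1 else 0.0

    null_by_size: dict[int, np.ndarray] = {}

    def null_for(k: int) -> np.ndarray:
        # groups of equal size share one null sample, so a smaller observed
        # similarity can never receive a larger p-value
        if k not in null_by_size:
            null = np.empty(n_perm)
            for b in range(n_perm):
                null[b] = mean_pairwise(rng.choice(n, size=k, replace=False))
            null_by_size[k] = null
        return null_by_size[k]

    rows = []
    for name, members in groups.items():
        members = list(members)
        missing = [m for m in members if m not in index]
        if missing:
            raise ValueError(f"group {name!r} has members outside the universe: "
                             f"{missing[:3]}")
        if len(set(members)) != len(members):
            raise ValueError(f"group {name!r} has duplicate members")
        k = len(members)
        if k < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
        observed = mean_pairwise(np.array([index[m] for m in members]))
        null = null_for(k)
        p = (1 + int((null <= observed).sum())) / (n_perm + 1)
        rows.append({
            "group": name,
            "size": k,
            "observed_similarity": observed,
            "p_value": p,
            "null_median": float(np.median(null)),
            "null_lo": float(np.quantile(null, 0.025)),
            "null_hi": float(np.quantile(null, 0.975)),
        })
    return pd.DataFrame(rows)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric with population N, successes K, draws n."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} impossible for N={N}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def family_enrichment(group: Collection[str], family_members: Collection[str],
                      population: Collection[str]) -> float:
    """Upper-tail hypergeometric p-value for family over-representation.

    ``population`` defines the urn (typically the miRNAs present in the
    analysed projection; alternatively all miRNAs passing the z-score
    threshold — the choice is the caller's).  The group must lie within the
    population; family members outside it are ignored.
    """
    pop = set(population)
    grp = set(group)
    if not grp <= pop:
        raise ValueError("group members outside the population")
    fam = set(family_members) & pop
    k = len(grp & fam)
    return hypergeom_upper_tail(k, len(pop), len(fam), len(grp))


def enrich_groups(groups: Mapping[str, Collection[str]],
                  families: Mapping[str, str],
                  population: Collection[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of every family present in each group.

    ``families`` maps miRNA id -> family label.  Returns one row per
    (group, family) combination with the counts N, K, n, k and the p-value.
    """
    pop = set(population)
    by_family: dict[str, set[str]] = {}
    for mirna, fam in families.items():
        if mirna in pop:
            by_family.setdefault(fam, set()).add(mirna)
    rows = []
    for name, members in groups.items():
        grp = set(members) & pop
        if not grp:
            continue
        seen = {families[m] for m in grp if m in families}
        for fam in sorted(seen):
            fam_set = by_family[fam]
            k = len(grp & fam_set)
            rows.append({
                "group": name,
                "family": fam,
                "population_size": len(pop),
                "family_in_population": len(fam_set),
                "group_size": len(grp),
                "family_in_group": k,
                "p_value": hypergeom_upper_tail(k, len(pop), len(fam_set), len(grp)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# input formats

def read_seed_records(path, families: Mapping[str, str] | None = None) -> list[SeedRecord]:
    """Load mature sequences from a 2-column TSV (id, sequence) or FASTA."""
    p = str(path)
    records: list[SeedRecord] = []
    families = families or {}
    if p.endswith((".fa", ".fasta", ".fna")):
        from Bio import SeqIO
        for rec in SeqIO.parse(p, "fasta"):
            records.append(SeedRecord(rec.id, str(rec.seq),
                                      families.get(rec.id)))
    else:
        with open(p) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in ("id", "mirna_id", "mirna"):
                    continue
                mirna_id, seq = fields[0], fields[1]
                records.append(SeedRecord(mirna_id, seq, families.get(mirna_id)))
    for rec in records:  # validate eagerly so bad input fails at load time
        rec.seed  # noqa: B018
    return records


def read_family_table(path) -> dict[str, str]:
    """2-column TSV (miRNA id, family) -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in ("id", "mirna_id", "mirna"):
                continue
            out[fields[0]] = fields[1]
    return out
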