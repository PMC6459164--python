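"""Synthetic cohort generators with planted ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — contaminated two-group expression with planted DEGs, planted
condition-specific bivariate dependences, a compartment-structured
interaction network with planted relocalization events, and
Dirichlet-multinomial V-J clonotype counts — and returns the truth needed
to score recovery. All generators are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hdcn._log import derive_seed, get_logger
from hdcn.containers import (
    COMPARTMENTS,
    MIXED,
    REFERENCE,
    ClonotypeTable,
    ExpressionMatrix,
    LocalizationAnnotation,
)

log = get_logger("hdcn.simulate")


@dataclass
class CohortTruth:
    pi_true: pd.Series  # per mixed sample, in [0, 0.95]
    deg_genes: dict[str, float]  # gene id -> signed log2 effect
    seed: int


@dataclass
class PairTruth:
    #: (gene_a, gene_b, condition of elevated dependence)
    planted_pairs: list[tuple[str, str, str]]
    seed: int


@dataclass
class RelocalizationTruth:
    #: protein -> (source compartment, destination compartment)
    relocated: dict[str, tuple[str, str]]
    seed: int


def _values_from_log2(z: np.ndarray) -> np.ndarray:
    """Map log2(x+1)-scale draws to the raw FPKM scale (non-negative)."""
    return np.maximum(0.0, 2.0**z - 1.0)


def simulate_expression_cohort(
    n_genes: int = 1000,
    n_mixed: int = 40,
    n_reference: int = 40,
    n_deg: int = 200,
    effect_log2: float = 1.0,
    pi_range: tuple[float, float] = (0.2, 0.6),
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Two-group log-normal cohort with per-sample reference contamination.

    Reference samples draw log2(x+1) values from Normal(mu_g, sigma_g) with
    mu_g ~ U(2, 8), sigma_g ~ U(0.3, 0.8), plus measurement noise of sd
    ``noise_sd``. The pure mixed-condition profile equals the reference
    profile except for ``n_deg`` planted genes shifted by +/- effect_log2
    (random sign). Each emitted mixed sample is, on the raw scale,
    pi_i * (reference draw) + (1 - pi_i) * (pure mixed draw) with
    pi_i ~ U(pi_range).
    """
    if n_deg > n_genes:
        raise ValueError("n_deg must not exceed n_genes")
    if not (0 <= pi_range[0] <= pi_range[1] <= 0.95):
        raise ValueError("pi_range must lie within [0, 0.95]")
    if effect_log2 <= 0:
        raise ValueError("effect_log2 must be positive")
    rng = np.random.default_rng(derive_seed(seed, "expression_cohort"))
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    mixed_ids = [f"mix{i:03d}" for i in range(1, n_mixed + 1)]
    ref_ids = [f"ref{i:03d}" for i in range(1, n_reference + 1)]

    mu = rng.uniform(2.0, 8.0, n_genes)
    sigma = rng.uniform(0.3, 0.8, n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    effect = np.zeros(n_genes)
    effect[deg_idx] = signs * effect_log2

    def draw(mu_vec: np.ndarray, n_cols: int) -> np.ndarray:
        z = rng.normal(mu_vec[:, None], sigma[:, None], (n_genes, n_cols))
        if noise_sd > 0:
            z += rng.normal(0.0, noise_sd, (n_genes, n_cols))
        return _values_from_log2(z)

    ref_values = draw(mu, n_reference)
    pi = rng.uniform(pi_range[0], pi_range[1], n_mixed)
    contamination = draw(mu, n_mixed)
    pure_mixed = draw(mu + effect, n_mixed)
    mixed_values = pi[None, :] * contamination + (1.0 - pi[None, :]) * pure_mixed

    values = pd.DataFrame(
        np.hstack([mixed_values, ref_values]),
        index=genes,
        columns=mixed_ids + ref_ids,
    )
    groups = {s: MIXED for s in mixed_ids} | {s: REFERENCE for s in ref_ids}
    truth = CohortTruth(
        pi_true=pd.Series(pi, index=mixed_ids, name="pi_true"),
        deg_genes={genes[i]: effect[i] for i in deg_idx},
        seed=seed,
    )
    return ExpressionMatrix(values, groups), truth


_FORMS = {
    "linear": lambda x: x,
    "quadratic": lambda x: 4.0 * (x - 0.5) ** 2,
    "sinusoidal": lambda x: np.sin(4.0 * np.pi * x),
}


def simulate_coexpression_cohort(
    n_pairs_dependent: int = 20,
    n_pairs_null: int = 80,
    n_samples_per_condition: int = 100,
    dependence_form: str = "linear",
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PairTruth]:
    """Gene pairs functionally dependent in exactly one condition.

    Each planted pair is y = f(x) + noise in its dependent condition
    (alternating between mixed and reference) and independent in the other;
    null pairs are independent in both. Latent variables are mapped
    affinely to a positive FPKM-like scale, which leaves MIC unchanged.
    """
    if dependence_form not in _FORMS:
        raise ValueError(f"dependence_form must be one of {sorted(_FORMS)}")
    if n_samples_per_condition < 10:
        raise ValueError("need at least 10 samples per condition for MIC")
    rng = np.random.default_rng(derive_seed(seed, "coexpression_cohort"))
    f = _FORMS[dependence_form]
    n_pairs = n_pairs_dependent + n_pairs_null
    n = n_samples_per_condition

    genes, planted = [], []
    blocks = {MIXED: [], REFERENCE: []}
    for p in range(n_pairs):
        ga, gb = f"p{p:04d}a", f"p{p:04d}b"
        genes += [ga, gb]
        dep_cond = None
        if p < n_pairs_dependent:
            dep_cond = MIXED if p % 2 == 0 else REFERENCE
            planted.append((ga, gb, dep_cond))
        for cond in (MIXED, REFERENCE):
            x = rng.uniform(0.0, 1.0, n)
            if cond == dep_cond:
                y = f(x) + rng.normal(0.0, noise_sd, n)
            else:
                y = f(rng.uniform(0.0, 1.0, n)) + rng.normal(0.0, noise_sd, n)
            blocks[cond].append(np.vstack([50.0 * x + 1.0, 20.0 * (y + 2.5)]))

    out = []
    for cond, prefix in ((MIXED, "mix"), (REFERENCE, "ref")):
        samples = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
        values = pd.DataFrame(
            np.vstack(blocks[cond]), index=genes, columns=samples
        )
        out.append(ExpressionMatrix(values, {s: cond for s in samples}))
    return out[0], out[1], PairTruth(planted_pairs=planted, seed=seed)


def simulate_network_with_localization(
    n_proteins: int = 100,
    n_compartments: int = 10,
    edge_density: float = 0.06,
    n_relocated: int = 5,
    coexpr_within: float = 0.85,
    coexpr_between: float = 0.15,
    n_samples: int = 60,
    seed: int = 0,
) -> tuple[
    nx.Graph,
    LocalizationAnnotation,
    ExpressionMatrix,
    ExpressionMatrix,
    RelocalizationTruth,
]:
    """Compartment-structured interaction network with planted relocations.

    Proteins are assigned evenly to the 10 compartments; edges are drawn
    preferentially within compartments (between/within odds equal to
    ``coexpr_between / coexpr_within``; with coexpr_between = 0 no
    cross-compartment edges exist). Expression is built from one latent
    factor per compartment per condition: a protein's log-scale profile is
    sqrt(w) * factor + sqrt(1-w) * noise with w = coexpr_within, so
    within-compartment pairs co-vary and cross-compartment pairs do not.
    Relocated proteins follow their source compartment's factor in the
    reference condition and their destination's in the mixed condition, and
    are additionally wired to partners in the destination compartment (a
    relocating protein interacts in both states). Annotations record the
    source compartment.
    """
    if n_compartments != 10:
        raise ValueError("the compartment vocabulary is fixed at 10 labels")
    if not 0 < coexpr_within <= 1 or coexpr_between >= coexpr_within:
        raise ValueError("need 0 < coexpr_between < coexpr_within <= 1")
    if n_relocated >= n_proteins:
        raise ValueError("n_relocated must be smaller than n_proteins")
    if n_proteins < 2 * n_compartments:
        raise ValueError("need at least 2 proteins per compartment")
    rng = np.random.default_rng(derive_seed(seed, "network_localization"))

    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    comp_of = {
        p: COMPARTMENTS[i % n_compartments]
        for i, p in enumerate(rng.permutation(proteins))
    }
    members: dict[str, list[str]] = {c: [] for c in COMPARTMENTS}
    for p in proteins:
        members[comp_of[p]].append(p)

    relocated_ids = list(rng.choice(proteins, size=n_relocated, replace=False))
    relocated: dict[str, tuple[str, str]] = {}
    for p in relocated_ids:
        src = comp_of[p]
        dest = str(rng.choice([c for c in COMPARTMENTS if c != src]))
        relocated[p] = (src, dest)

    # edge probabilities solving the overall density for the given odds
    frac_within = sum(
        len(m) * (len(m) - 1) / 2 for m in members.values()
    ) / (n_proteins * (n_proteins - 1) / 2)
    odds = coexpr_between / coexpr_within
    p_between = edge_density / (frac_within * (1.0 / odds) + (1 - frac_within)) if odds > 0 else 0.0
    p_within = p_between / odds if odds > 0 else edge_density / frac_within
    p_within = min(1.0, p_within)

    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            a, b = proteins[i], proteins[j]
            p_edge = p_within if comp_of[a] == comp_of[b] else p_between
            if rng.random() < p_edge:
                graph.add_edge(a, b)
    # guarantee every protein has some same-compartment partners, and give
    # relocated proteins destination-side partners
    for p in proteins:
        pool = [q for q in members[comp_of[p]] if q != p]
        want = [q for q in rng.permutation(pool)[:3]]
        for q in want:
            graph.add_edge(p, q)
    for p, (_, dest) in relocated.items():
        pool = [q for q in members[dest] if q != p]
        for q in rng.permutation(pool)[:3]:
            graph.add_edge(p, q)

    w = coexpr_within
    samples = {
        MIXED: [f"mix{i:03d}" for i in range(1, n_samples + 1)],
        REFERENCE: [f"ref{i:03d}" for i in range(1, n_samples + 1)],
    }
    matrices = {}
    for cond in (MIXED, REFERENCE):
        factors = {c: rng.standard_normal(n_samples) for c in COMPARTMENTS}
        Z = np.empty((n_proteins, n_samples))
        for i, p in enumerate(proteins):
            c = comp_of[p]
            if p in relocated and cond == MIXED:
                c = relocated[p][1]
            Z[i] = np.sqrt(w) * factors[c] + np.sqrt(1 - w) * rng.standard_normal(
                n_samples
            )
        values = pd.DataFrame(
            _values_from_log2(6.0 + 1.5 * Z), index=proteins, columns=samples[cond]
        )
        matrices[cond] = ExpressionMatrix(
            values, {s: cond for s in samples[cond]}
        )

    annotations = LocalizationAnnotation({p: comp_of[p] for p in proteins})
    truth = RelocalizationTruth(relocated=relocated, seed=seed)
    return graph, annotations, matrices[MIXED], matrices[REFERENCE], truth


_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _in_frame_junction(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(4, 7))
    return "".join(rng.choice(_SAFE_CODONS, n_codons))


def _out_of_frame_junction(rng: np.random.Generator) -> str:
    junction = _in_frame_junction(rng)
    if rng.random() < 0.5:
        # frameshift: length not divisible by 3
        return junction + str(rng.choice(list("ACGT")))
    # internal stop codon in frame 0
    pos = 3 * int(rng.integers(0, len(junction) // 3))
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return junction[:pos] + stop + junction[pos + 3 :]


def simulate_repertoire(
    n_samples_per_group: int = 20,
    n_v: int = 8,
    n_j: int = 5,
    concentration_low: float = 5.0,
    concentration_high: float = 50.0,
    reads_per_sample: int = 2000,
    frameshift_rate: float = 0.2,
    seed: int = 0,
) -> tuple[ClonotypeTable, pd.Series, str]:
    """Dirichlet-multinomial V-J clonotype counts with a diversity contrast.

    Per-sample combination abundances are Multinomial(reads_per_sample, p)
    with p ~ Dirichlet(concentration / K) over the K = n_v * n_j
    combinations; the mixed group uses ``concentration_high`` (more even,
    hence higher diversity), the reference group ``concentration_low``.
    Each combination emits one junction sequence per sample; a
    ``frameshift_rate`` fraction of junctions is out of frame (length not
    divisible by 3, or an in-frame stop codon).

    Returns (table, group label per sample, name of the higher-diversity
    group).
    """
    if n_v * n_j < 2:
        raise ValueError("need at least 2 V-J combinations")
    if concentration_low > concentration_high:
        raise ValueError("concentration_low must not exceed concentration_high")
    rng = np.random.default_rng(derive_seed(seed, "repertoire"))
    combos = [
        (f"V{v + 1:02d}", f"J{j + 1}") for v in range(n_v) for j in range(n_j)
    ]
    k = len(combos)
    rows = []
    sample_groups = {}
    for group, conc, prefix in (
        (MIXED, concentration_high, "mix"),
        (REFERENCE, concentration_low, "ref"),
    ):
        for i in range(1, n_samples_per_group + 1):
            sample = f"{prefix}{i:03d}"
            sample_groups[sample] = group
            p = rng.dirichlet(np.full(k, conc / k))
            counts = rng.multinomial(reads_per_sample, p)
            used = set()
            for (v, j), count in zip(combos, counts):
                if count == 0:
                    continue
                while True:
                    if rng.random() < frameshift_rate:
                        junction = _out_of_frame_junction(rng)
                    else:
                        junction = _in_frame_junction(rng)
                    if junction not in used:
                        used.add(junction)
                        break
                rows.append(
                    {
                        "sample_id": sample,
                        "v_gene": v,
                        "j_gene": j,
                        "junction_nt": junction,
                        "count": int(count),
                    }
                )
    table = ClonotypeTable(pd.DataFrame(rows, columns=list(ClonotypeTable.COLUMNS)))
    return table, pd.Series(sample_groups, name="group"), MIXED


__all__ = [
    "CohortTruth",
    "PairTruth",
    "RelocalizationTruth",
    "simulate_expression_cohort",
    "simulate_coexpression_cohort",
    "simulate_network_with_localization",
    "simulate_repertoire",
]
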