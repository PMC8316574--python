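"""Synthetic fixtures with known ground truth for every pipeline stage.

Every generator is a pure function of (config, seed): the same inputs give
byte-identical outputs.  The generators emulate the statistical structure
of the real inputs — replicate isotope ratios with multiplicative noise,
ortholog alignments realizing prescribed conservation patterns on a random
species tree, per-site annotation tables with a planted kinase enrichment,
and class-separated feature tables — without attempting to mimic real
sequence composition or kinome topology.  Truth tables are returned so
downstream calls can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import core_io
from .core_io import (
    AnnotationBundle,
    IsoformQuant,
    PhosphositeRecord,
    PhyloTree,
    ProteinRecord,
)
from .conservation import OrthologAlignment
from .features import FEATURE_COLUMNS

AMINO_ACIDS_NO_STY = list("ACDEFGHIKLMNPQVW")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkSim:
    """Feature/label generator for model-level tests.

    ``logistic`` (default): iid standard-normal features with labels drawn
    from a logistic model with known coefficients, so coefficient recovery
    is well posed.  ``gaussian-shift``: a single feature shifted by ``d``
    in the positive class, giving the analytic AUC Phi(d / sqrt(2)).
    """

    n_samples: int = 5000
    mode: str = "logistic"
    beta: tuple[float, ...] = (0.8, -0.5, 0.3, 1.0, -0.2, 0.6, 0.0, -0.9)
    intercept: float = 0.0
    d: float = 1.19
    n_per_class: int | None = None  # gaussian-shift: samples per class


@dataclass
class QuantSim:
    """Replicate isotope-ratio generator with planted fold changes.

    Unregulated isoforms have ratios log-normal around 1 in every genotype;
    regulated isoforms have the test-genotype location multiplied (hyper)
    or divided (hypo) by ``fold``.  ``noise_sd`` is the standard deviation
    of the natural-log ratio, the usual scale for multiplicative MS error.
    """

    n_isoforms: int = 500
    replicates: int = 4
    fraction_regulated: float = 0.1
    fold: float = 2.0
    noise_sd: float = 0.1
    test_genotype: str = "daf-2"
    control_genotype: str = "WT"
    auxiliary_genotypes: tuple[str, ...] = ("daf-16", "daf-16;daf-2")


@dataclass
class TreeSim:
    n_species: int = 7
    min_branch: float = 0.1
    max_branch: float = 2.0
    reference_species: str = "ref"


@dataclass
class EnrichSim:
    """Annotation generator with one kinase's targets planted among the
    regulated sites at a configured enrichment ratio."""

    n_kinases: int = 20
    edges_per_kinase: int = 200
    planted_kinase: str = "KF01"
    target_e_ratio: float = 3.0


@dataclass
class FixtureSim:
    """End-to-end fixture: proteins, sites, quant, annotations, MSAs, tree.

    ``n_positives`` sites are designated functional; their annotations are
    drawn from separated distributions (more kinase edges, higher
    conservation, more frequent acetylation co-occurrence) so the trained
    scorer has signal to find.
    """

    n_proteins: int = 40
    n_sites: int = 200
    n_positives: int = 30
    protein_length: tuple[int, int] = (80, 200)
    # class-conditional annotation parameters (negatives, positives);
    # moderate shifts so the benchmark is separable but not trivially so
    ukf_lambda: tuple[float, float] = (0.8, 2.0)
    conserved_frac: tuple[float, float] = (0.3, 0.55)
    asc_prob: tuple[float, float] = (0.15, 0.35)
    rsa_beta: tuple[tuple[float, float], tuple[float, float]] = ((2, 4), (3, 3))
    #: fraction of planted regulated isoforms drawn from the functional
    #: (positive) sites, so prioritized and regulated sets overlap
    regulated_positive_bias: float = 0.5
    n_pathways: int = 12
    quant: QuantSim = field(default_factory=QuantSim)
    tree: TreeSim = field(default_factory=TreeSim)
    # enrichment design scaled to the fixture: each kinase targets a quarter
    # of the sites; the planted kinase concentrates on hypo-regulated sites
    enrich: EnrichSim = field(
        default_factory=lambda: EnrichSim(edges_per_kinase=50, target_e_ratio=4.0)
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_benchmark(
    cfg: BenchmarkSim, seed: int
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Generate (features, labels, true coefficients) per the config mode."""
    rng = np.random.default_rng(seed)
    if cfg.mode == "gaussian-shift":
        n = cfg.n_per_class or cfg.n_samples // 2
        x_neg = rng.normal(0.0, 1.0, size=n)
        x_pos = rng.normal(cfg.d, 1.0, size=n)
        X = pd.DataFrame({"x": np.concatenate([x_neg, x_pos])})
        y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
        return X, y, np.array([cfg.d])
    if cfg.mode == "logistic":
        beta = np.asarray(cfg.beta, dtype=float)
        X = rng.normal(0.0, 1.0, size=(cfg.n_samples, beta.size))
        logits = X @ beta + cfg.intercept
        y = (rng.uniform(size=cfg.n_samples) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
        cols = [f"f{i}" for i in range(beta.size)]
        return pd.DataFrame(X, columns=cols), y, beta
    raise ValueError(f"unknown benchmark mode {cfg.mode!r}")


def simulate_quant_table(
    cfg: QuantSim,
    seed: int,
    site_ids: list[str] | None = None,
    bias_ids: list[str] | None = None,
    bias_frac: float = 0.0,
) -> tuple[list[IsoformQuant], pd.DataFrame]:
    """Generate isoform ratio data with planted directions.

    Returns the isoforms and a truth table (isoform_id, direction) where
    direction is "hyper", "hypo", or "none".  Planted regulated isoforms
    split evenly between directions.  If ``site_ids`` is given, isoforms
    are built on those sites; otherwise synthetic single-site ids are used.
    ``bias_frac`` of the regulated isoforms are drawn from ``bias_ids``
    (e.g. the functional sites), the rest uniformly from the remainder.
    """
    rng = np.random.default_rng(seed)
    if site_ids is None:
        isoform_ids = [f"Q{i:04d}:S{10 + i}" for i in range(cfg.n_isoforms)]
    else:
        if len(site_ids) < cfg.n_isoforms:
            raise ValueError("not enough site ids for requested isoforms")
        isoform_ids = list(site_ids[: cfg.n_isoforms])
    n_reg = int(round(cfg.fraction_regulated * cfg.n_isoforms))
    if cfg.fold == 1.0:
        n_reg = 0  # a fold of 1 plants no effect: the truth is all "none"
    if bias_ids and bias_frac > 0.0:
        biased = [i for i, iso in enumerate(isoform_ids) if iso in set(bias_ids)]
        rest = [i for i in range(cfg.n_isoforms) if i not in set(biased)]
        n_biased = min(int(round(bias_frac * n_reg)), len(biased))
        reg_idx = np.concatenate([
            rng.choice(biased, size=n_biased, replace=False),
            rng.choice(rest, size=n_reg - n_biased, replace=False),
        ]).astype(int)
    else:
        reg_idx = rng.choice(cfg.n_isoforms, size=n_reg, replace=False)
    directions = np.array(["none"] * cfg.n_isoforms, dtype=object)
    half = n_reg // 2
    directions[reg_idx[:half]] = "hyper"
    directions[reg_idx[half:]] = "hypo"

    genotypes = [cfg.test_genotype, cfg.control_genotype, *cfg.auxiliary_genotypes]
    log_fold = math.log(cfg.fold)
    isoforms = []
    for i, isoform_id in enumerate(isoform_ids):
        ratios = {}
        for genotype in genotypes:
            mu = 0.0
            if genotype == cfg.test_genotype:
                if directions[i] == "hyper":
                    mu = log_fold
                elif directions[i] == "hypo":
                    mu = -log_fold
            ratios[genotype] = list(
                np.exp(rng.normal(mu, cfg.noise_sd, size=cfg.replicates))
            )
        isoforms.append(IsoformQuant(isoform_id=isoform_id, ratios=ratios))
    truth = pd.DataFrame({"isoform_id": isoform_ids, "direction": directions})
    return isoforms, truth


def simulate_tree(cfg: TreeSim, seed: int) -> tuple[str, list[str]]:
    """Random rooted binary tree over the analysis species.

    Topology by random sequential pair-joining; branch lengths uniform in
    [min_branch, max_branch].  Returns (newick string, species labels);
    the reference species is the first label.
    """
    rng = np.random.default_rng(seed)
    labels = [cfg.reference_species] + [
        f"sp{i:02d}" for i in range(1, cfg.n_species)
    ]

    def bl() -> float:
        return float(rng.uniform(cfg.min_branch, cfg.max_branch))

    nodes = [f"{label}:{bl():.6f}" for label in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{bl():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = f"({nodes[0]},{nodes[1]});"
    return newick, labels


def simulate_msa(
    protein: ProteinRecord,
    sites: list[PhosphositeRecord],
    conserved_pattern: dict[int, set[str]],
    species: list[str],
    reference_species: str,
    seed: int,
) -> OrthologAlignment:
    """Build an ungapped ortholog alignment realizing a conservation pattern.

    ``conserved_pattern`` maps site position -> species (beyond the
    reference) carrying a phosphoacceptor there.  Non-conserved species get
    alanine at site columns; non-site columns copy the reference, so the
    conserved set at each site column is exactly the requested one.
    """
    rng = np.random.default_rng(seed)
    length = len(protein.sequence)
    rows = {reference_species: protein.sequence}
    site_res = {s.position: s.residue for s in sites}
    for sp in species:
        if sp == reference_species:
            continue
        chars = list(protein.sequence)
        for pos, conserved in conserved_pattern.items():
            if pos < 1 or pos > length:
                raise ValueError(f"pattern position {pos} outside protein")
            chars[pos - 1] = site_res.get(pos, "A") if sp in conserved else "A"
        rows[sp] = "".join(chars)
    return OrthologAlignment(rows=rows, reference_species=reference_species)


def simulate_annotations(
    cfg: EnrichSim,
    sites: list[PhosphositeRecord],
    regulated_site_ids: set[str],
    seed: int,
) -> set[tuple[str, str]]:
    """Kinase-site edge table with one planted enriched kinase.

    Each kinase receives ``edges_per_kinase`` target sites.  Null kinases
    sample uniformly from all sites; the planted kinase draws each edge
    from the regulated set with probability target_e_ratio * M/N (its
    expected E-ratio is then the configured target), the rest uniformly
    from unregulated sites.
    """
    rng = np.random.default_rng(seed)
    all_ids = [s.site_id for s in sites]
    regulated = sorted(regulated_site_ids & set(all_ids))
    unregulated = sorted(set(all_ids) - set(regulated))
    N = len(all_ids)
    edges: set[tuple[str, str]] = set()
    for i in range(cfg.n_kinases):
        kinase = f"KF{i + 1:02d}"
        n_edges = min(cfg.edges_per_kinase, N)
        if kinase == cfg.planted_kinase and regulated:
            p_reg = min(1.0, cfg.target_e_ratio * len(regulated) / N)
            n_reg = int(rng.binomial(n_edges, p_reg))
            n_reg = min(n_reg, len(regulated))
            n_unreg = min(n_edges - n_reg, len(unregulated))
            chosen = [
                regulated[j]
                for j in rng.choice(len(regulated), size=n_reg, replace=False)
            ] + [
                unregulated[j]
                for j in rng.choice(len(unregulated), size=n_unreg, replace=False)
            ]
        else:
            chosen = [
                all_ids[j] for j in rng.choice(N, size=n_edges, replace=False)
            ]
        edges.update((kinase, sid) for sid in chosen)
    return edges


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS_NO_STY, size=length))


@dataclass
class Fixture:
    """In-memory fixture with every input the pipeline consumes."""

    proteins: list[ProteinRecord]
    sites: list[PhosphositeRecord]
    positives: list[str]
    isoforms: list[IsoformQuant]
    quant_truth: pd.DataFrame
    bundle: AnnotationBundle
    alignments: dict[str, OrthologAlignment]
    newick: str
    conserved_patterns: dict[str, dict[int, set[str]]]
    pathways: pd.DataFrame
    config: FixtureSim


def simulate_fixture(cfg: FixtureSim, seed: int) -> Fixture:
    """Generate a complete, internally consistent synthetic study."""
    rng = np.random.default_rng(seed)
    species_newick, species = simulate_tree(cfg.tree, seed=int(rng.integers(2**31)))
    ref = cfg.tree.reference_species

    # proteins with phosphosites planted at known positions
    proteins: list[ProteinRecord] = []
    sites: list[PhosphositeRecord] = []
    sites_per_protein = cfg.n_sites // cfg.n_proteins
    extra = cfg.n_sites - sites_per_protein * cfg.n_proteins
    for p in range(cfg.n_proteins):
        length = int(rng.integers(*cfg.protein_length))
        seq = list(_random_protein(rng, length))
        n_here = sites_per_protein + (1 if p < extra else 0)
        positions = sorted(
            int(x) + 1 for x in rng.choice(length, size=n_here, replace=False)
        )
        acc = f"P{p:03d}"
        for pos in positions:
            residue = str(rng.choice(["S", "T", "Y"], p=[0.6, 0.3, 0.1]))
            seq[pos - 1] = residue
            sites.append(PhosphositeRecord(accession=acc, position=pos, residue=residue))
        proteins.append(ProteinRecord(accession=acc, sequence="".join(seq)))

    pos_idx = rng.choice(len(sites), size=cfg.n_positives, replace=False)
    positive_ids = sorted(sites[i].site_id for i in pos_idx)
    is_positive = {s.site_id: (s.site_id in set(positive_ids)) for s in sites}

    # quantitation with planted folds, isoforms built on the real site ids
    site_order = [s.site_id for s in sites]
    quant_cfg = QuantSim(
        **{**asdict(cfg.quant), "n_isoforms": min(cfg.quant.n_isoforms, len(site_order))}
    )
    isoforms, quant_truth = simulate_quant_table(
        quant_cfg,
        seed=int(rng.integers(2**31)),
        site_ids=site_order,
        bias_ids=positive_ids,
        bias_frac=cfg.regulated_positive_bias,
    )
    regulated_ids = {
        row.isoform_id
        for row in quant_truth.itertuples(index=False)
        if row.direction != "none"
    }
    hypo_ids = {
        row.isoform_id
        for row in quant_truth.itertuples(index=False)
        if row.direction == "hypo"
    }

    # conservation patterns: positives conserved across more species
    patterns: dict[str, dict[int, set[str]]] = {}
    alignments: dict[str, OrthologAlignment] = {}
    others = [sp for sp in species if sp != ref]
    by_protein: dict[str, list[PhosphositeRecord]] = {}
    for s in sites:
        by_protein.setdefault(s.accession, []).append(s)
    for prot in proteins:
        pattern: dict[int, set[str]] = {}
        for s in by_protein.get(prot.accession, []):
            frac = cfg.conserved_frac[int(is_positive[s.site_id])]
            n_cons = int(rng.binomial(len(others), frac))
            chosen = rng.choice(len(others), size=n_cons, replace=False)
            pattern[s.position] = {others[j] for j in chosen}
        patterns[prot.accession] = pattern
        alignments[prot.accession] = simulate_msa(
            prot, by_protein.get(prot.accession, []), pattern, species, ref,
            seed=int(rng.integers(2**31)),
        )

    # annotation bundle: kinase edges (planted enrichment), acetyl, domains,
    # rsa/ss; positives drawn from shifted distributions
    bundle = AnnotationBundle()
    bundle.kinase_edges = simulate_annotations(
        cfg.enrich, sites, hypo_ids, seed=int(rng.integers(2**31))
    )
    # extra class-separating edges for positives
    for s in sites:
        lam = cfg.ukf_lambda[int(is_positive[s.site_id])]
        for k in range(int(rng.poisson(lam))):
            kinase = f"KF{int(rng.integers(1, cfg.enrich.n_kinases + 1)):02d}"
            bundle.kinase_edges.add((kinase, s.site_id))
    seq_by_acc = {p.accession: p.sequence for p in proteins}
    for s in sites:
        if rng.uniform() < cfg.asc_prob[int(is_positive[s.site_id])]:
            length = len(seq_by_acc[s.accession])
            lo = max(1, s.position - 15)
            hi = min(length, s.position + 15)
            bundle.acetyl_sites.add((s.accession, int(rng.integers(lo, hi + 1))))
        a, b = cfg.rsa_beta[int(is_positive[s.site_id])]
        bundle.rsa[s.site_id] = float(rng.beta(a, b))
        alpha0 = (2.0, 2.0, 4.0) if not is_positive[s.site_id] else (3.0, 1.5, 3.5)
        probs = rng.dirichlet(alpha0)
        bundle.ss_probs[s.site_id] = (float(probs[0]), float(probs[1]), float(probs[2]))
    # domains: one or two spans per protein with partner counts
    domain_counter = 0
    for prot in proteins:
        for _ in range(int(rng.integers(1, 3))):
            length = len(prot.sequence)
            start = int(rng.integers(1, max(2, length - 20)))
            end = min(length, start + int(rng.integers(15, 60)))
            domain_id = f"DM{domain_counter:04d}"
            domain_counter += 1
            bundle.domain_spans.append((prot.accession, start, end, domain_id))
            bundle.domain_partner_counts[domain_id] = int(rng.integers(0, 8))

    # gene -> pathway annotation
    rows = []
    for prot in proteins:
        for pw in rng.choice(
            cfg.n_pathways, size=int(rng.integers(0, 4)), replace=False
        ):
            rows.append((prot.accession, f"PW{pw + 1:02d}"))
    pathways = pd.DataFrame(rows, columns=["gene", "pathway"])

    return Fixture(
        proteins=proteins,
        sites=sites,
        positives=positive_ids,
        isoforms=isoforms,
        quant_truth=quant_truth,
        bundle=bundle,
        alignments=alignments,
        newick=species_newick,
        conserved_patterns=patterns,
        pathways=pathways,
        config=cfg,
    )


def write_fixture(fixture: Fixture, directory: str | Path) -> dict[str, Path]:
    """Write a fixture directory consumable by the pipeline.

    Layout: sites.tsv, proteins.fasta, quant.tsv, tree.nwk, positives.txt,
    pathways.tsv, annotations/ (six TSVs), msa/{accession}.fasta, and truth
    tables (truth_quant.tsv) plus a config snapshot (config.json).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sites"] = directory / "sites.tsv"
    core_io.write_site_table(fixture.sites, fixture.proteins, paths["sites"])
    paths["proteins"] = directory / "proteins.fasta"
    core_io.write_fasta(fixture.proteins, paths["proteins"])
    paths["quant"] = directory / "quant.tsv"
    core_io.write_quant_table(fixture.isoforms, paths["quant"])
    paths["tree"] = directory / "tree.nwk"
    paths["tree"].write_text(fixture.newick + "\n")
    paths["positives"] = directory / "positives.txt"
    paths["positives"].write_text("\n".join(fixture.positives) + "\n")
    paths["pathways"] = directory / "pathways.tsv"
    core_io.write_tsv(fixture.pathways, paths["pathways"])
    paths["annotations"] = directory / "annotations"
    core_io.write_annotations(fixture.bundle, paths["annotations"])
    msa_dir = directory / "msa"
    msa_dir.mkdir(exist_ok=True)
    for acc, aln in fixture.alignments.items():
        records = [ProteinRecord(sp, row) for sp, row in sorted(aln.rows.items())]
        core_io.write_fasta(records, msa_dir / f"{acc}.fasta")
    paths["msa_dir"] = msa_dir
    paths["truth_quant"] = directory / "truth_quant.tsv"
    core_io.write_tsv(fixture.quant_truth, paths["truth_quant"])
    paths["config"] = directory / "config.json"
    paths["config"].write_text(json.dumps(asdict(fixture.config), indent=2, default=list))
    return paths
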