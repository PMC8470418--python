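"""Synthetic inputs with planted structure for the whole pipeline.

Every input the screen consumes can be generated here with the
statistical structure the analysis assumes: differential-expression
tables with planted co-overexpression modules, clade tables with planted
gene losses and calibrated sequence divergences, phylogenetic profiles
with planted clade patterns, and interaction edge lists with planted
communities.  A single integer seed drives one named pseudo-random
stream per generator, so adding a generator never perturbs the others.

`fixture_paper_counts` builds a fixed-seed bundle whose category counts
match a published multiciliation screen: 634 focal-clade gene losses,
104 high- and 623 mild-divergence calls proteome-wide (1361 flagged in a
21,044-gene proteome); 41 + 10 + 63 of them overexpressed in at least
two experiments (114 candidates, 122 after adding eight known
multiciliation genes); a 919-node interaction network containing 57 list
genes; and a curated evidence block for eleven poorly characterized
candidate genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .conservation import (
    ABSENT,
    CONSERVED,
    HIGH_DIVERGENCE,
    MILD_DIVERGENCE,
    ConservationParams,
)
from .enrichment import AnnotationMap
from .expression_screen import ExperimentTable
from .integration import DEFAULT_KNOWN_GENES, CandidateEvidence
from .phylo_profiling import (
    ABSENT_FOCAL_CLADE,
    ABSENT_NONCILIATED,
    CHORDATE_RESTRICTED,
    METAZOA_RESTRICTED,
    NONE_PATTERN,
    PRESENT_BROADLY,
)

FIXTURE_SEED = 20210921

BACKGROUND = "background"

#: fraction of the species panel allotted to each band (3-level nesting:
#: supergroup > phylum-level clade > subclade); invented study conditions
_PANEL_BANDS = (
    # (fraction, supergroup, clade, subclade, ciliated, focal)
    (0.15, "Protista", "Protista", "Protista", True, False),
    (0.12, "Fungi", "Fungi", "Fungi", False, False),
    (0.12, "Archaeplastida", "Archaeplastida", "Archaeplastida", False, False),
    (0.06, "Metazoa", "Nematoda", "Nematoda", False, False),
    (0.20, "Metazoa", "Lophotrochozoa", "Lophotrochozoa", True, False),
    (0.03, "Metazoa", "Chordata", "Tunicata", True, False),
    (0.24, "Metazoa", "Chordata", "Vertebrata", True, False),
    (0.08, "Metazoa", "Chordata", "Otomorpha", True, True),
)

PROFILE_PATTERNS = (
    PRESENT_BROADLY,
    ABSENT_NONCILIATED,
    ABSENT_FOCAL_CLADE,
    CHORDATE_RESTRICTED,
    METAZOA_RESTRICTED,
)


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-overexpression module."""

    size: int
    active_experiments: frozenset
    activation_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("module size must be >= 0")
        if not 0 <= self.activation_prob <= 1:
            raise ValueError("activation_prob must be in [0, 1]")
        object.__setattr__(self, "active_experiments", frozenset(self.active_experiments))


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic screen."""

    n_genes: int = 21044
    n_experiments: int = 10
    module_specs: list = field(
        default_factory=lambda: [
            ModuleSpec(40, frozenset({0, 1, 2}), 0.9),
            ModuleSpec(40, frozenset({3, 4, 5}), 0.9),
            ModuleSpec(40, frozenset({1, 6, 7}), 0.9),
            ModuleSpec(40, frozenset({8, 9}), 0.9),
        ]
    )
    background_overexpr_prob: float = 0.05
    n_focal_species: int = 8
    n_reference_species: int = 12
    n_profile_species: int = 711
    planted_losses: int = 634
    planted_high_div: int = 104
    planted_mild_div: int = 623
    profile_patterns: list = field(
        default_factory=lambda: [(p, 40) for p in PROFILE_PATTERNS]
    )
    profile_noise: float = 0.05
    community_sizes: list = field(default_factory=lambda: [12, 15, 18])
    intra_edge_prob: float = 0.9
    inter_edge_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_overexpr_prob", "profile_noise",
                     "intra_edge_prob", "inter_edge_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_experiments", "n_focal_species",
                     "n_reference_species", "n_profile_species",
                     "planted_losses", "planted_high_div", "planted_mild_div"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.module_specs = [
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.module_specs
        ]
        if sum(m.size for m in self.module_specs) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        for m in self.module_specs:
            bad = [e for e in m.active_experiments if not 0 <= e < self.n_experiments]
            if bad:
                raise ValueError(f"module active experiments out of range: {bad}")

    def to_yaml(self, path) -> None:
        data = {
            k: v for k, v in self.__dict__.items()
            if k not in ("module_specs", "profile_patterns")
        }
        data["module_specs"] = [
            {"size": m.size, "active_experiments": sorted(m.active_experiments),
             "activation_prob": m.activation_prob}
            for m in self.module_specs
        ]
        data["profile_patterns"] = [list(p) for p in self.profile_patterns]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["module_specs"] = [
            ModuleSpec(m["size"], frozenset(m["active_experiments"]),
                       m["activation_prob"])
            for m in data.get("module_specs", [])
        ]
        data["profile_patterns"] = [
            (p[0], int(p[1])) for p in data.get("profile_patterns", [])
        ]
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted labels keyed by gene."""

    module_of: dict = field(default_factory=dict)
    conservation_of: dict = field(default_factory=dict)
    pattern_of: dict = field(default_factory=dict)
    community_of: dict = field(default_factory=dict)


def _stream(seed: int, name: str) -> np.random.Generator:
    """One named, seed-derived pseudo-random stream per generator."""
    key = zlib.adler32(name.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def experiment_ids(n: int) -> list[str]:
    return [f"exp{i + 1:02d}" for i in range(n)]


# ---------------------------------------------------------------------------
# differential-expression tables

def _plant_de_tables(
    genes: list[str],
    exp_ids: list[str],
    active: np.ndarray,  # genes x experiments boolean
    rng: np.random.Generator,
) -> list[ExperimentTable]:
    tables = []
    n = len(genes)
    for j, exp in enumerate(exp_ids):
        logfc = rng.uniform(-2.0, 0.9, n)
        pval = rng.uniform(0.0, 1.0, n)
        on = active[:, j]
        n_on = int(on.sum())
        logfc[on] = rng.uniform(1.2, 4.0, n_on)
        pval[on] = rng.uniform(1e-8, 0.01, n_on)
        tables.append(
            ExperimentTable(
                experiment_id=exp,
                data=pd.DataFrame(
                    {"gene_id": genes, "logfc": np.round(logfc, 4),
                     "pvalue": pval}
                ),
            )
        )
    return tables


def simulate_de_experiments(
    config: SimulationConfig,
) -> tuple[list[ExperimentTable], GroundTruth]:
    """Planted co-overexpression modules plus sporadic background calls.

    Genes of a planted module exceed the overexpression thresholds in each
    of the module's active experiments with probability
    ``activation_prob`` and stay sub-threshold elsewhere; background genes
    exceed the thresholds in at most one (randomly chosen) experiment.
    """
    rng = _stream(config.seed, "de")
    genes = _gene_names(config.n_genes)
    exp_ids = experiment_ids(config.n_experiments)
    active = np.zeros((config.n_genes, config.n_experiments), dtype=bool)
    gt = GroundTruth()

    cursor = 0
    for k, spec in enumerate(config.module_specs):
        idx = np.arange(cursor, cursor + spec.size)
        cursor += spec.size
        for g in idx:
            gt.module_of[genes[g]] = f"M{k + 1}"
        for e in sorted(spec.active_experiments):
            fire = rng.random(spec.size) < spec.activation_prob
            active[idx[fire], e] = True

    bg_idx = np.arange(cursor, config.n_genes)
    for g in bg_idx:
        gt.module_of[genes[g]] = BACKGROUND
    fire = rng.random(len(bg_idx)) < config.background_overexpr_prob
    choice = rng.integers(0, config.n_experiments, len(bg_idx))
    active[bg_idx[fire], choice[fire]] = True

    tables = _plant_de_tables(genes, exp_ids, active, rng)
    return tables, gt


# ---------------------------------------------------------------------------
# clade tables

def _clade_rows(
    genes_by_category: dict[str, list[str]],
    rng: np.random.Generator,
    n_focal: int,
    n_ref: int,
    params: ConservationParams,
) -> pd.DataFrame:
    """Rows of a clade table with deterministic classification margins.

    High-divergence genes are planted at D = z_hi + 2 * (z_hi - z_lo),
    mild ones at the midpoint of [z_lo, z_hi), conserved ones near D = 0;
    losses have no focal ortholog and reference presence >= 80%.
    """
    if n_focal < 2 or n_ref < 2:
        raise ValueError("clade sizes must be >= 2 for divergence statistics")
    target_d = {
        ABSENT: None,
        HIGH_DIVERGENCE: params.z_hi + 2.0 * params.gap,
        MILD_DIVERGENCE: (params.z_hi + params.z_lo) / 2.0,
        CONSERVED: 0.0,
    }
    rows = []
    for category in (ABSENT, HIGH_DIVERGENCE, MILD_DIVERGENCE, CONSERVED):
        for gene in genes_by_category.get(category, []):
            ref = np.clip(rng.normal(90.0, 2.0, n_ref), 60.0, 100.0)
            ref = np.round(ref, 3)
            if category == ABSENT:
                ref_presence = int(rng.integers(int(np.ceil(0.8 * n_ref)), n_ref + 1))
                rows.append((gene, 0, n_focal, ref_presence, n_ref, [], list(ref)))
                continue
            d = target_d[category]
            if category == CONSERVED:
                d = float(rng.normal(0.0, 0.2))
            sd = ref.std(ddof=1)
            focal_mean = ref.mean() - d * sd
            focal = [round(float(focal_mean), 6)] * n_focal
            rows.append((gene, n_focal, n_focal, n_ref, n_ref, focal, list(ref)))
    return pd.DataFrame(
        rows,
        columns=["gene", "focal_presence", "n_focal", "ref_presence", "n_ref",
                 "focal_identities", "ref_identities"],
    )


def simulate_clade_tables(
    config: SimulationConfig,
    params: ConservationParams = ConservationParams(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Clade table with planted losses, divergences and conserved genes."""
    rng = _stream(config.seed, "clade")
    genes = _gene_names(config.n_genes)
    n_abs, n_hi, n_mild = (
        config.planted_losses, config.planted_high_div, config.planted_mild_div
    )
    if n_abs + n_hi + n_mild > config.n_genes:
        raise ValueError("planted conservation categories exceed n_genes")
    cats = {
        ABSENT: genes[:n_abs],
        HIGH_DIVERGENCE: genes[n_abs:n_abs + n_hi],
        MILD_DIVERGENCE: genes[n_abs + n_hi:n_abs + n_hi + n_mild],
        CONSERVED: genes[n_abs + n_hi + n_mild:],
    }
    table = _clade_rows(cats, rng, config.n_focal_species,
                        config.n_reference_species, params)
    gt = GroundTruth()
    for cat, gs in cats.items():
        for g in gs:
            gt.conservation_of[g] = cat
    return table, gt


# ---------------------------------------------------------------------------
# phylogenetic profiles

def build_species_panel(n_species: int) -> pd.DataFrame:
    """Species panel with nested clade labels and ciliated/focal flags."""
    counts = [int(round(frac * n_species)) for frac, *_ in _PANEL_BANDS]
    counts[-1] = n_species - sum(counts[:-1])
    if counts[-1] < 1:
        raise ValueError("panel too small for the clade bands")
    rows = []
    i = 0
    for (frac, sg, clade, sub, cil, focal), c in zip(_PANEL_BANDS, counts):
        for _ in range(c):
            rows.append((f"sp{i + 1:04d}", sg, clade, sub, cil, focal))
            i += 1
    return pd.DataFrame(
        rows, columns=["species", "supergroup", "clade", "subclade",
                       "ciliated", "focal"],
    )


def _pattern_row(pattern: str, panel: pd.DataFrame) -> np.ndarray:
    sub = panel["subclade"].to_numpy()
    sg = panel["supergroup"].to_numpy()
    clade = panel["clade"].to_numpy()
    ciliated = panel["ciliated"].to_numpy(bool)
    if pattern == PRESENT_BROADLY:
        return np.ones(len(panel), dtype=int)
    if pattern == ABSENT_NONCILIATED:
        return ciliated.astype(int)
    if pattern == ABSENT_FOCAL_CLADE:
        return (sub == "Vertebrata").astype(int)
    if pattern == CHORDATE_RESTRICTED:
        return (clade == "Chordata").astype(int)
    if pattern == METAZOA_RESTRICTED:
        return ((sg == "Metazoa") & (sub != "Nematoda")).astype(int)
    raise ValueError(f"unknown profile pattern: {pattern}")


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Gene x species presence matrix with planted clade patterns.

    Returns the binary profile matrix, the species panel (whose label
    columns define the clade masks) and the planted pattern per gene.
    Entries are flipped independently at rate ``profile_noise``.
    """
    rng = _stream(config.seed, "profiles")
    panel = build_species_panel(config.n_profile_species)
    total = sum(c for _, c in config.profile_patterns)
    if total > config.n_genes:
        raise ValueError("profile pattern counts exceed n_genes")
    genes = _gene_names(total)
    gt = GroundTruth()
    rows = []
    i = 0
    for pattern, count in config.profile_patterns:
        base = _pattern_row(pattern, panel)
        for _ in range(count):
            rows.append(base.copy())
            gt.pattern_of[genes[i]] = pattern
            i += 1
    X = np.array(rows, dtype=int)
    if config.profile_noise > 0:
        flips = rng.random(X.shape) < config.profile_noise
        X = np.where(flips, 1 - X, X)
    matrix = pd.DataFrame(X, index=genes, columns=panel["species"])
    matrix.index.name = "gene"
    return matrix, panel, gt


# ---------------------------------------------------------------------------
# interaction network

def simulate_network(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Stochastic-block edge list with planted communities.

    Within-community pairs are connected with probability
    ``intra_edge_prob`` and high confidence scores; cross-community pairs
    with probability ``inter_edge_prob`` and low scores.
    """
    if any(s < 3 for s in config.community_sizes):
        raise ValueError("community sizes must be >= 3")
    if config.intra_edge_prob <= config.inter_edge_prob:
        raise ValueError("intra_edge_prob must exceed inter_edge_prob")
    rng = _stream(config.seed, "network")
    sizes = list(config.community_sizes)
    n = sum(sizes)
    nodes = [f"N{i:04d}" for i in range(n)]
    block = np.repeat(np.arange(len(sizes)), sizes)
    gt = GroundTruth()
    for node, b in zip(nodes, block):
        gt.community_of[node] = int(b) + 1
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if block[i] == block[j]:
                if rng.random() < config.intra_edge_prob:
                    rows.append((nodes[i], nodes[j], round(rng.uniform(0.85, 0.99), 3)))
            elif rng.random() < config.inter_edge_prob:
                rows.append((nodes[i], nodes[j], round(rng.uniform(0.40, 0.70), 3)))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return edges, gt


# ---------------------------------------------------------------------------
# the deterministic paper-counts fixture

ELEVEN_CANDIDATES = (
    "C1orf189", "C20orf85", "C5orf24", "KIAA1841", "FAM181A", "IQCK",
    "LRRC43", "DYDC1", "CFAP47", "ANKRD60", "TEX43",
)

#: printed per-gene evidence for the curated shortlist:
#: (expression cluster, conservation category, network cluster, profile cluster)
_CURATED_EVIDENCE = {
    "C1orf189": (13, ABSENT, None, 9),
    "C20orf85": (18, ABSENT, None, 9),
    "C5orf24": (3, MILD_DIVERGENCE, None, 8),
    "KIAA1841": (19, MILD_DIVERGENCE, None, 5),
    "FAM181A": (9, HIGH_DIVERGENCE, None, 8),
    "IQCK": (12, MILD_DIVERGENCE, None, 7),
    "LRRC43": (22, MILD_DIVERGENCE, None, 8),
    "DYDC1": (8, MILD_DIVERGENCE, None, 8),
    "CFAP47": (12, ABSENT, None, 5),
    "ANKRD60": (17, ABSENT, None, 9),
    "TEX43": (18, ABSENT, None, 9),
}

#: profile clusters of the fixture mapped to the clade pattern they carry
_PROFILE_CLUSTER_PATTERNS = {
    5: ABSENT_NONCILIATED,
    7: METAZOA_RESTRICTED,
    8: CHORDATE_RESTRICTED,
    9: ABSENT_FOCAL_CLADE,
}

#: curated shortlist genes found in the multiciliated signature group
_MULTICIL_FIVE = ("C1orf189", "FAM181A", "IQCK", "DYDC1", "CFAP47")

MULTICIL_GROUP = "multiciliated"

_PROTEOME_SIZE = 21044
_N_FOCAL, _N_REF = 8, 12


@dataclass
class FixtureBundle:
    """Deterministic full-input bundle with planted headline counts."""

    de_tables: list
    clade_table: pd.DataFrame
    profile_presence: pd.DataFrame
    panel: pd.DataFrame
    network_edges: pd.DataFrame
    target_list: list  # the 122 genes handed to the network step
    annotations: AnnotationMap
    known_genes: tuple
    ground_truth: GroundTruth
    proteome: list


def _fixture_gene_sets() -> dict:
    eleven_absent = ["C1orf189", "C20orf85", "CFAP47", "ANKRD60", "TEX43"]
    eleven_mild = ["C5orf24", "KIAA1841", "IQCK", "LRRC43", "DYDC1"]
    cand_absent = eleven_absent + [f"CANDA{i:03d}" for i in range(36)]
    cand_high = ["FAM181A"] + [f"CANDH{i:03d}" for i in range(9)]
    cand_mild = eleven_mild + [f"CANDM{i:03d}" for i in range(58)]
    ret = [f"RETC{i:04d}" for i in range(300)]
    singles = [f"SGL{i:04d}" for i in range(110)]
    flagged_bg = {
        ABSENT: [f"FLGA{i:04d}" for i in range(634 - len(cand_absent) - 1)],
        HIGH_DIVERGENCE: [f"FLGH{i:04d}" for i in range(104 - len(cand_high) - 1)],
        MILD_DIVERGENCE: [f"FLGM{i:04d}" for i in range(623 - len(cand_mild))],
    }
    named = (
        cand_absent + cand_high + cand_mild + list(DEFAULT_KNOWN_GENES) + ret
        + singles + flagged_bg[ABSENT] + flagged_bg[HIGH_DIVERGENCE]
        + flagged_bg[MILD_DIVERGENCE]
    )
    filler = [f"BG{i:05d}" for i in range(_PROTEOME_SIZE - len(named))]
    return {
        "cand_absent": cand_absent,
        "cand_high": cand_high,
        "cand_mild": cand_mild,
        "ret": ret,
        "singles": singles,
        "flagged_bg": flagged_bg,
        "filler": filler,
        "proteome": named + filler,
    }


def _fixture_modules(sets: dict) -> list[tuple[str, list[str], tuple[int, ...]]]:
    ca, ch, cm, ret = (sets["cand_absent"], sets["cand_high"], sets["cand_mild"],
                       sets["ret"])
    return [
        ("M1", list(_MULTICIL_FIVE) + ca[5:15] + cm[5:20] + ret[:20],
         (0, 1, 2, 3, 4, 5, 6)),
        ("M2", ["C20orf85", "TEX43", "ANKRD60"] + ca[15:41] + ch[1:10] + ret[20:50],
         (2, 3, 6, 7)),
        ("M3", ["C5orf24", "KIAA1841", "LRRC43"] + cm[20:63] + ret[50:100], (0, 8)),
        ("M4", ret[100:200], (4, 5)),
        ("M5", ret[200:300], (1, 9)),
    ]


def fixture_paper_counts() -> FixtureBundle:
    """Deterministic input bundle reproducing the published category counts."""
    sets = _fixture_gene_sets()
    gt = GroundTruth()
    exp_ids = experiment_ids(10)

    # --- expression tables: planted modules (activation prob 1) + singles
    modules = _fixture_modules(sets)
    module_genes: list[str] = []
    for _, genes, _ in modules:
        module_genes.extend(genes)
    assert len(module_genes) == len(set(module_genes))
    singles = sets["singles"] + list(DEFAULT_KNOWN_GENES)
    de_genes = module_genes + singles + sets["filler"][:200]
    active = np.zeros((len(de_genes), 10), dtype=bool)
    pos = {g: i for i, g in enumerate(de_genes)}
    for name, genes, exps in modules:
        for g in genes:
            gt.module_of[g] = name
            for e in exps:
                active[pos[g], e] = True
    for i, g in enumerate(singles):
        gt.module_of[g] = BACKGROUND
        active[pos[g], i % 10] = True
    for g in sets["filler"][:200]:
        gt.module_of[g] = BACKGROUND
    rng = _stream(FIXTURE_SEED, "fixture-de")
    de_tables = _plant_de_tables(de_genes, exp_ids, active, rng)

    # --- clade table over the full proteome
    cats = {
        ABSENT: sets["cand_absent"] + ["CDC20B"] + sets["flagged_bg"][ABSENT],
        HIGH_DIVERGENCE: sets["cand_high"] + ["CCNO"]
        + sets["flagged_bg"][HIGH_DIVERGENCE],
        MILD_DIVERGENCE: sets["cand_mild"] + sets["flagged_bg"][MILD_DIVERGENCE],
    }
    flagged_all = set().union(*cats.values())
    cats[CONSERVED] = [g for g in sets["proteome"] if g not in flagged_all]
    assert len(cats[ABSENT]) == 634
    assert len(cats[HIGH_DIVERGENCE]) == 104
    assert len(cats[MILD_DIVERGENCE]) == 623
    rng = _stream(FIXTURE_SEED, "fixture-clade")
    clade_table = _clade_rows(cats, rng, _N_FOCAL, _N_REF, ConservationParams())
    for cat, genes in cats.items():
        for g in genes:
            gt.conservation_of[g] = cat

    # --- target list and interaction network (57 of the 122 have edges)
    target_list = sorted(
        set(sets["cand_absent"] + sets["cand_high"] + sets["cand_mild"])
        | set(DEFAULT_KNOWN_GENES)
    )
    list57 = (
        list(DEFAULT_KNOWN_GENES) + sets["cand_absent"][15:41]
        + sets["cand_high"][1:10] + sets["cand_mild"][20:34]
    )
    assert len(list57) == 57
    externals = [f"EXT{i:04d}" for i in range(862)]
    list_per_block = [8, 6, 6, 6, 6, 5, 5, 5, 5, 5]
    ext_per_block = [87, 87, 87, 87, 86, 86, 86, 86, 85, 85]
    rng = _stream(FIXTURE_SEED, "fixture-network")
    rows = []
    li = ei = 0
    blocks = []
    for b, (nl, ne) in enumerate(zip(list_per_block, ext_per_block)):
        bl = list57[li:li + nl]
        be = externals[ei:ei + ne]
        li += nl
        ei += ne
        blocks.append((bl, be))
        for node in bl + be:
            gt.community_of[node] = b + 1
        for ext in be:  # two high-confidence anchors into the list
            anchors = rng.choice(len(bl), size=2, replace=False)
            for a in anchors:
                rows.append((ext, bl[a], round(rng.uniform(0.90, 0.99), 3)))
        for i in range(len(bl)):  # list-list edges at the permissive threshold
            for j in range(i + 1, len(bl)):
                if rng.random() < 0.6:
                    rows.append((bl[i], bl[j], round(rng.uniform(0.70, 0.95), 3)))
        for i in range(len(be)):
            for j in range(i + 1, len(be)):
                if rng.random() < 0.04:
                    rows.append((be[i], be[j], round(rng.uniform(0.90, 0.99), 3)))
    for b1 in range(len(blocks)):  # sparse low-confidence cross-block noise
        for b2 in range(b1 + 1, len(blocks)):
            for _ in range(3):
                u = blocks[b1][1][int(rng.integers(len(blocks[b1][1])))]
                v = blocks[b2][1][int(rng.integers(len(blocks[b2][1])))]
                rows.append((u, v, round(rng.uniform(0.30, 0.65), 3)))
    network_edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])

    # --- phylogenetic profiles for targets and network genes (984 total)
    panel = build_species_panel(711)
    profile_genes = sorted(set(target_list) | set(externals) | set(list57))
    assert len(profile_genes) == 984
    pattern_map: dict[str, str] = {}
    for g in ELEVEN_CANDIDATES:
        pattern_map[g] = _PROFILE_CLUSTER_PATTERNS[_CURATED_EVIDENCE[g][3]]
    known_patterns = {
        "CDC20B": ABSENT_FOCAL_CLADE, "CCNO": CHORDATE_RESTRICTED,
        "GEMC1": CHORDATE_RESTRICTED, "CEP63": CHORDATE_RESTRICTED,
        "CCDC78": CHORDATE_RESTRICTED, "CEP152": METAZOA_RESTRICTED,
        "E2F4": PRESENT_BROADLY, "E2F5": PRESENT_BROADLY,
    }
    pattern_map.update(known_patterns)
    cycle = list(PROFILE_PATTERNS)
    for i, g in enumerate(profile_genes):
        pattern_map.setdefault(g, cycle[i % len(cycle)])
    X = np.array([_pattern_row(pattern_map[g], panel) for g in profile_genes])
    profile_presence = pd.DataFrame(X, index=profile_genes, columns=panel["species"])
    profile_presence.index.name = "gene"
    gt.pattern_of.update(pattern_map)

    # --- annotations: known genes and conserved retained genes carry terms,
    #     the curated shortlist carries none
    ret = sets["ret"]
    terms = {
        "T0001": frozenset(list(DEFAULT_KNOWN_GENES) + ret[:100]),
        "T0002": frozenset(list(DEFAULT_KNOWN_GENES) + ret[100:200]),
        "T0003": frozenset(ret[200:300]),
        "T0004": frozenset(sets["cand_mild"][20:50] + sets["cand_absent"][20:36]),
    }
    names = {
        "T0001": "cilium organization", "T0002": "cell cycle",
        "T0003": "establishment of localization", "T0004": "protein binding",
    }
    annotations = AnnotationMap(terms=terms, names=names,
                                population=frozenset(sets["proteome"]))

    return FixtureBundle(
        de_tables=de_tables,
        clade_table=clade_table,
        profile_presence=profile_presence,
        panel=panel,
        network_edges=network_edges,
        target_list=target_list,
        annotations=annotations,
        known_genes=DEFAULT_KNOWN_GENES,
        ground_truth=gt,
        proteome=sets["proteome"],
    )


def curated_shortlist_records(include_decoys: bool = False) -> list[CandidateEvidence]:
    """Evidence records for the eleven curated candidates (plus decoys).

    Each record carries the published per-gene evidence: expression
    cluster, conservation category, no network cluster, profile cluster
    (with the matching clade pattern) and zero annotations.  Decoy records
    each violate exactly one prioritization criterion.
    """
    overexpr = {"M1": 7, "M2": 4, "M3": 2}
    gene_module = {g: "M1" for g in _MULTICIL_FIVE}
    gene_module.update({"C20orf85": "M2", "TEX43": "M2", "ANKRD60": "M2"})
    gene_module.update({"C5orf24": "M3", "KIAA1841": "M3", "LRRC43": "M3"})
    records = []
    for gene in ELEVEN_CANDIDATES:
        expr_cluster, category, net_cluster, prof_cluster = _CURATED_EVIDENCE[gene]
        module = gene_module[gene]
        records.append(
            CandidateEvidence(
                gene=gene,
                overexpr_count=overexpr[module],
                expression_cluster=expr_cluster,
                cluster_signature_group=(
                    MULTICIL_GROUP if gene in _MULTICIL_FIVE else "other"
                ),
                conservation_category=category,
                network_cluster=net_cluster,
                profile_cluster=prof_cluster,
                profile_patterns=(_PROFILE_CLUSTER_PATTERNS[prof_cluster],),
                annotation_count=0,
            )
        )
    if include_decoys:
        records.extend(
            [
                CandidateEvidence(
                    gene="DECOY_ANNOTATED", overexpr_count=5, expression_cluster=8,
                    cluster_signature_group=MULTICIL_GROUP,
                    conservation_category=ABSENT, profile_cluster=9,
                    profile_patterns=(ABSENT_FOCAL_CLADE,), annotation_count=7,
                ),
                CandidateEvidence(
                    gene="DECOY_CONSERVED", overexpr_count=5, expression_cluster=8,
                    cluster_signature_group=MULTICIL_GROUP,
                    conservation_category=CONSERVED, profile_cluster=9,
                    profile_patterns=(ABSENT_FOCAL_CLADE,), annotation_count=0,
                ),
                CandidateEvidence(
                    gene="DECOY_NONCILIARY", overexpr_count=5, expression_cluster=8,
                    cluster_signature_group=MULTICIL_GROUP,
                    conservation_category=ABSENT, profile_cluster=2,
                    profile_patterns=(NONE_PATTERN,), annotation_count=0,
                ),
                CandidateEvidence(
                    gene="DECOY_BROADLY_PRESENT", overexpr_count=5,
                    expression_cluster=8, cluster_signature_group="other",
                    conservation_category=MILD_DIVERGENCE, profile_cluster=1,
                    profile_patterns=(PRESENT_BROADLY,), annotation_count=0,
                ),
            ]
        )
    return records
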