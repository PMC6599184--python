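"""Synthetic study generator with planted ground truth.

Emulates a two-strain (BALB/c, C57BL/6) x three-treatment (CON, AMP+NEO, ERY)
x two-timepoint (pre, post) mouse study, n mice per strain per treatment
(default 6):

* 16S OTU counts: per-strain log-normal base composition, per-mouse
  log-normal composition offsets, strain / treatment x time / three-way
  effects as log2 fold changes on the composition, Dirichlet-multinomial
  sampling at a per-sample depth uniform in a configured range.
* NanoString-style miRNA counts: low-mean negatives, a positive-control
  ladder with per-lane scale jitter, log-normal endogenous probes with
  planted group fold changes, and probes coupled monotonically to taxa.
* A bacterial gene catalog of i.i.d. uniform ACGT genes with planted
  miRNA-complementary sites and a configurable unclassified fraction.
* Gut-barrier data: log-normal FITC permeability with a Gaussian-copula
  coupling to a taxon's post-treatment abundance, and qPCR Ct records.

Every generator takes one seed; independent streams are derived internally
as ``default_rng([seed, stream_index])`` with a fixed stream index per
component, so adding taxa or probes never re-couples unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_STRAINS,
    GeneCatalog,
    Lineage,
    MirnaCounts,
    OtuTable,
    SampleMeta,
    TREATMENTS,
    parse_lineage,
)
from .targets import revcomp

_GENERA = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae",
     "Prevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae",
     "Parabacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae",
     "Bacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae",
     "Alistipes"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae",
     "Blautia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae",
     "Roseburia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae",
     "Oscillospira"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae",
     "Clostridium"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae",
     "Lactobacillus"),
    ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae",
     "Staphylococcus"),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales",
     "Verrucomicrobiaceae", "Akkermansia"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
     "Enterobacteriaceae", "Escherichia"),
    ("Actinobacteria", "Actinobacteria", "Coriobacteriales",
     "Coriobacteriaceae", "Slackia"),
    ("Tenericutes", "Erysipelotrichi", "Erysipelotrichales",
     "Erysipelotrichaceae", "Allobaculum"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptococcaceae", None),
    ("Cyanobacteria", "4C0d-2", "YS2", None, None),
]


def default_taxon_lineages(n_taxa: int) -> list[Lineage]:
    """Realistic gut lineages cycling through a genus pool."""
    out = []
    for i in range(n_taxa):
        p, c, o, f, g = _GENERA[i % len(_GENERA)]
        suffix = "" if i < len(_GENERA) else f"_{i // len(_GENERA)}"
        text = (f"p_{p};c_{c};o_{o};f_{f or ''};"
                f"g_{(g or '') and g + suffix}")
        out.append(parse_lineage(text))
    return out


@dataclass
class CommunityConfig:
    """Study-design and noise parameters for the 16S simulator.

    Defaults follow the emulated study: 6 mice per strain per treatment, a
    per-sample read depth between 11,353 and 139,193, a log-normal base
    composition (sigma 1.5 across taxa), per-mouse composition scatter
    (sigma 0.6 per taxon) and mild Dirichlet-multinomial overdispersion.
    Effects are log2 fold changes on the underlying composition;
    ``base_log2_taxa`` pins a taxon's baseline (log2 scale, replacing its
    random draw) so planted effects can deliberately target a consistently
    common taxon — relative abundance of an affected taxon is otherwise a
    lottery of the log-normal baseline.
    """

    n_mice_per_group: int = 6
    n_taxa: int = 30
    depth_range: tuple[int, int] = (11353, 139193)
    base_log2_taxa: dict[int, float] = field(default_factory=dict)
    strain_effect_taxa: dict[int, float] = field(default_factory=dict)
    treatment_effect_taxa: dict[tuple[int, str], float] = \
        field(default_factory=dict)
    strain_interaction_taxa: dict[int, float] = field(default_factory=dict)
    overdispersion: float = 0.02
    base_sigma: float = 1.5
    mouse_sigma: float = 0.6
    strains: tuple[str, str] = DEFAULT_STRAINS
    seed: int = 0

    def validate(self) -> None:
        if self.depth_range[0] < 1000:
            raise ValueError("minimum depth must be >= 1000")
        for t in self.base_log2_taxa:
            self._check_taxon(t)
        for t in self.strain_effect_taxa:
            self._check_taxon(t)
        for t, trt in self.treatment_effect_taxa:
            self._check_taxon(t)
            if trt not in TREATMENTS:
                raise ValueError(f"unknown treatment {trt!r}")
        for t in self.strain_interaction_taxa:
            self._check_taxon(t)

    def _check_taxon(self, t: int) -> None:
        if not 0 <= t < self.n_taxa:
            raise ValueError(f"effect references absent taxon {t}")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, for recovery tests."""

    strain_effect_taxa: list[int] = field(default_factory=list)
    treatment_time_taxa: list[tuple[int, str]] = field(default_factory=list)
    three_way_taxa: list[int] = field(default_factory=list)
    mirna_de_probes: dict[str, float] = field(default_factory=dict)
    mirna_taxon_couplings: list[tuple[str, str, int]] = \
        field(default_factory=list)
    planted_sites: list[dict] = field(default_factory=list)
    permeability_coupling: tuple[str, float] | None = None
    qpcr_effects: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.strain_effect_taxa:
            rows.append({"kind": "strain_effect", "key": str(t)})
        for t, trt in self.treatment_time_taxa:
            rows.append({"kind": "treatment_time", "key": f"{t}|{trt}"})
        for t in self.three_way_taxa:
            rows.append({"kind": "three_way", "key": str(t)})
        for probe, fc in self.mirna_de_probes.items():
            rows.append({"kind": "mirna_de", "key": f"{probe}|{fc}"})
        for probe, taxon, sign in self.mirna_taxon_couplings:
            rows.append({"kind": "mirna_taxon",
                         "key": f"{probe}|{taxon}|{sign}"})
        for site in self.planted_sites:
            rows.append({"kind": "planted_site",
                         "key": f"{site['mirna_id']}|{site['gene_id']}"})
        if self.permeability_coupling:
            rows.append({"kind": "permeability",
                         "key": f"{self.permeability_coupling[0]}|"
                                f"{self.permeability_coupling[1]}"})
        return pd.DataFrame(rows, columns=["kind", "key"])


def _stream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def simulate_community(
    config: CommunityConfig,
) -> tuple[OtuTable, OtuTable, list[SampleMeta], PlantedTruth]:
    """Generate paired pre/post OTU tables for the full factorial design.

    Returns (pre table, post table, metadata for all samples, truth). Both
    tables share sample ordering by mouse; sample ids are ``<mouse>_pre`` and
    ``<mouse>_post``.
    """
    config.validate()
    rng_base = _stream(config.seed, 0)
    rng_mouse = _stream(config.seed, 1)
    rng_depth = _stream(config.seed, 2)
    rng_dirich = _stream(config.seed, 3)

    n_taxa = config.n_taxa
    base_log = rng_base.normal(0.0, config.base_sigma, size=n_taxa)
    for t, lfc in config.base_log2_taxa.items():
        base_log[t] = lfc * np.log(2.0)
    strain_shift = np.zeros(n_taxa)
    for t, lfc in config.strain_effect_taxa.items():
        strain_shift[t] = lfc * np.log(2.0)

    mice = []
    for strain in config.strains:
        for trt in TREATMENTS:
            for k in range(config.n_mice_per_group):
                tag = trt.replace("+", "")
                mice.append((f"{strain[:1]}_{tag}_{k}", strain, trt))

    meta: list[SampleMeta] = []
    pre_counts = np.zeros((len(mice), n_taxa), dtype=np.int64)
    post_counts = np.zeros((len(mice), n_taxa), dtype=np.int64)
    for i, (mouse, strain, trt) in enumerate(mice):
        log_abund = base_log.copy()
        if strain == config.strains[1]:
            log_abund = log_abund + strain_shift
        log_abund = log_abund + rng_mouse.normal(
            0.0, config.mouse_sigma, size=n_taxa)

        post_shift = np.zeros(n_taxa)
        for (t, etrt), lfc in config.treatment_effect_taxa.items():
            if etrt == trt:
                post_shift[t] += lfc * np.log(2.0)
        if strain == config.strains[1] and trt != "CON":
            for t, lfc in config.strain_interaction_taxa.items():
                post_shift[t] += lfc * np.log(2.0)

        for tp, shift, out in (("pre", 0.0, pre_counts),
                               ("post", post_shift, post_counts)):
            comp = np.exp(log_abund + shift)
            comp = comp / comp.sum()
            alpha = comp / config.overdispersion
            p = rng_dirich.dirichlet(alpha)
            depth = int(rng_depth.integers(config.depth_range[0],
                                           config.depth_range[1] + 1))
            out[i] = rng_dirich.multinomial(depth, p)
            meta.append(SampleMeta(
                sample_id=f"{mouse}_{tp}", mouse_id=mouse, strain=strain,
                treatment=trt, timepoint=tp,
            ))

    lineages = default_taxon_lineages(n_taxa)
    otu_ids = [f"OTU_{i:04d}" for i in range(n_taxa)]
    pre_ids = [m.sample_id for m in meta if m.timepoint == "pre"]
    post_ids = [m.sample_id for m in meta if m.timepoint == "post"]
    pre = OtuTable(pre_ids, otu_ids, pre_counts, lineages)
    post = OtuTable(post_ids, otu_ids, post_counts, lineages)
    truth = PlantedTruth(
        strain_effect_taxa=sorted(config.strain_effect_taxa),
        treatment_time_taxa=sorted(config.treatment_effect_taxa),
        three_way_taxa=sorted(config.strain_interaction_taxa),
    )
    return pre, post, meta, truth


def combine_tables(pre: OtuTable, post: OtuTable) -> OtuTable:
    """Stack pre and post tables (shared OTU axis) into one table."""
    assert pre.otu_ids == post.otu_ids
    return OtuTable(
        pre.sample_ids + post.sample_ids, list(pre.otu_ids),
        np.vstack([pre.counts, post.counts]), list(pre.lineages),
    )


def simulate_mirna(
    n_probes: int = 200,
    n_neg: int = 6,
    n_pos: int = 6,
    groups: dict[str, str] | None = None,
    de_probes: dict[str, float] | None = None,
    coupling: dict[tuple[str, str], int] | None = None,
    relabund: pd.DataFrame | None = None,
    base_log2_mean: float = 8.0,
    noise_sd: float = 0.35,
    seed: int = 0,
) -> tuple[MirnaCounts, PlantedTruth]:
    """NanoString-style counts with planted fold changes and taxon couplings.

    ``groups`` maps sample id -> group label (e.g. strain); ``de_probes``
    maps probe id -> log2 fold change of the second sorted group over the
    first. ``coupling`` maps (probe, taxon column) -> +1/-1: the probe's
    counts become a monotone (rank-preserving, log-linear) transform of that
    taxon's relative abundance plus log-normal noise. Negative probes are
    low-mean Poisson; positive probes follow a fixed ladder with per-lane
    scale jitter.
    """
    if n_neg < 2 or n_pos < 2:
        raise ValueError(">= 2 negative and >= 2 positive probes required")
    de_probes = de_probes or {}
    coupling = coupling or {}
    if coupling and relabund is None:
        raise ValueError("couplings require a relative-abundance table")
    if groups is None:
        if relabund is None:
            raise ValueError("provide groups and/or relabund to fix samples")
        samples = [str(s) for s in relabund.index]
        groups = {s: "all" for s in samples}
    else:
        samples = list(groups)
    for (_, taxon) in coupling:
        if taxon not in relabund.columns:
            raise ValueError(f"coupling to absent taxon {taxon!r}")

    probe_ids = [f"miR-{i:03d}" for i in range(n_probes)]
    for p in list(de_probes) + [p for p, _ in coupling]:
        if p not in probe_ids:
            raise ValueError(f"unknown probe {p!r}")
    levels = sorted(set(groups.values()))
    rng = _stream(seed, 10)

    n_lanes = len(samples)
    lane_scale = np.exp(rng.normal(0.0, 0.05, size=n_lanes))
    endo = np.empty((n_probes, n_lanes))
    probe_mu = rng.normal(base_log2_mean, 1.5, size=n_probes)
    for j, s in enumerate(samples):
        mu = probe_mu.copy()
        if len(levels) == 2 and groups[s] == levels[1]:
            for p, lfc in de_probes.items():
                mu[probe_ids.index(p)] += lfc
        endo[:, j] = np.exp2(mu + rng.normal(0, noise_sd, size=n_probes))
    for (p, taxon), sign in coupling.items():
        i = probe_ids.index(p)
        vals = relabund.loc[samples, taxon].to_numpy(float)
        log_rel = np.log2(vals + 1e-9)
        centered = sign * (log_rel - log_rel.mean())
        endo[i] = np.exp2(base_log2_mean + centered
                          + rng.normal(0, noise_sd / 4, size=n_lanes))
    endo = endo * lane_scale[None, :]

    neg = rng.poisson(8.0, size=(n_neg, n_lanes)).astype(float)
    ladder = np.array([8000, 2000, 500, 125, 32, 8], dtype=float)
    pos_base = np.resize(ladder, n_pos)
    pos = pos_base[:, None] * lane_scale[None, :] * \
        np.exp(rng.normal(0, 0.02, size=(n_pos, n_lanes)))
    lig = np.array([600.0, 300.0])[:, None] * lane_scale[None, :] * \
        np.exp(rng.normal(0, 0.02, size=(2, n_lanes)))

    counts = np.vstack([endo, neg, pos, lig])
    ids = (probe_ids + [f"NEG_{i}" for i in range(n_neg)]
           + [f"POS_{i}" for i in range(n_pos)] + ["LIG_0", "LIG_1"])
    classes = (["endogenous"] * n_probes + ["negative"] * n_neg
               + ["positive"] * n_pos + ["ligation"] * 2)
    mc = MirnaCounts(ids, classes, samples, np.round(counts))
    truth = PlantedTruth(
        mirna_de_probes=dict(de_probes),
        mirna_taxon_couplings=[(p, t, s) for (p, t), s in coupling.items()],
    )
    return mc, truth


def simulate_catalog(
    n_genes: int = 1000,
    length_range: tuple[int, int] = (300, 1500),
    taxa_pool: list[Lineage] | None = None,
    planted_sites: list[tuple[str, str, str, int, int, str]] | None = None,
    frac_unclassified: float = 0.322,
    seed: int = 0,
) -> tuple[GeneCatalog, PlantedTruth]:
    """Uniform-ACGT gene catalog with planted miRNA-complementary sites.

    ``planted_sites`` entries are (mirna_id, mirna_seq, taxon_genus,
    site_len, n_copies, strand): each copy embeds the reverse complement
    (strand '-') or the verbatim sequence (strand '+') of a ``site_len``
    suffix window of the miRNA into its own fresh gene annotated with the
    given genus. The default unclassified fraction mirrors a catalog where
    about a third of genes carry no taxonomy.
    """
    planted_sites = planted_sites or []
    if not 0 <= frac_unclassified <= 1:
        raise ValueError("frac_unclassified must lie in [0, 1]")
    if taxa_pool is None:
        taxa_pool = default_taxon_lineages(len(_GENERA))
    rng = _stream(seed, 20)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)

    def random_gene(length: int) -> str:
        return rng.choice(alphabet, size=length).tobytes().decode("ascii")

    gene_ids, seqs, lineages, annotations = [], {}, {}, {}
    for i in range(n_genes):
        gid = f"GENE_{i:06d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gene_ids.append(gid)
        seqs[gid] = random_gene(length)
        if rng.random() >= frac_unclassified:
            lineages[gid] = taxa_pool[int(rng.integers(len(taxa_pool)))]
        if rng.random() < 0.5:
            annotations[gid] = f"COG{int(rng.integers(100, 5000)):04d}"

    truth = PlantedTruth()
    for k, (mid, mseq, genus, site_len, n_copies, strand) in \
            enumerate(planted_sites):
        mseq = mseq.upper().replace("U", "T")
        if site_len > len(mseq):
            raise ValueError(f"site length {site_len} exceeds miRNA length")
        window = mseq[-site_len:]
        insert = revcomp(window) if strand == "-" else window
        lin = next((l for l in taxa_pool if l.genus == genus), None)
        for c in range(n_copies):
            gid = f"PLANT_{k:03d}_{c}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if site_len > length:
                raise ValueError("site longer than gene")
            seq = random_gene(length)
            pos = int(rng.integers(0, length - site_len + 1))
            seqs[gid] = seq[:pos] + insert + seq[pos + site_len:]
            gene_ids.append(gid)
            if lin is not None:
                lineages[gid] = lin
            truth.planted_sites.append({
                "mirna_id": mid, "gene_id": gid, "taxon": genus,
                "site_len": site_len, "strand": strand, "position": pos,
            })
    return GeneCatalog(gene_ids, seqs, lineages, annotations), truth


def simulate_barrier(
    meta: list[SampleMeta],
    relabund: pd.DataFrame | None = None,
    coupling_taxon: str | None = None,
    coupling_rho: float = 0.0,
    qpcr_effects: dict[tuple[str, str, str], float] | None = None,
    fitc_log_mean: float = 0.0,
    fitc_log_sd: float = 0.45,
    treatment_shift: float = -0.5,
    seed: int = 0,
):
    """Per-mouse FITC permeability and qPCR Ct records.

    FITC normalized values are log-normal per strain/treatment (antibiotic
    arms shifted by ``treatment_shift`` on the log scale, emulating barrier
    tightening); when ``coupling_taxon`` is set the values share a Gaussian
    copula of strength ``coupling_rho`` with that taxon's post-treatment
    relative abundance. ``qpcr_effects`` maps (gene, strain, treatment) ->
    log2 expression change versus the strain's control group.

    Returns (permeability DataFrame, qPCR DataFrame, PlantedTruth).
    """
    if not -1.0 <= coupling_rho <= 1.0:
        raise ValueError("coupling_rho must lie in [-1, 1]")
    qpcr_effects = qpcr_effects or {}
    rng = _stream(seed, 30)
    post = [m for m in meta if m.timepoint == "post"]
    mice = sorted({m.mouse_id for m in post})
    info = {m.mouse_id: m for m in post}

    if coupling_taxon is not None:
        if relabund is None or coupling_taxon not in relabund.columns:
            raise ValueError(f"unknown coupling taxon {coupling_taxon!r}")
        # abundance rows may be keyed by post-sample id or by mouse id
        def _lookup(m: str) -> float:
            key = info[m].sample_id if info[m].sample_id in relabund.index \
                else m
            return float(relabund.loc[key, coupling_taxon])

        rel = np.array([_lookup(m) for m in mice], dtype=float)
        from scipy import stats as _st
        ranks = _st.rankdata(rel)
        z_taxon = _st.norm.ppf(ranks / (len(rel) + 1))
        eps = rng.normal(size=len(mice))
        z_fitc = coupling_rho * z_taxon + \
            np.sqrt(max(0.0, 1 - coupling_rho ** 2)) * eps
    else:
        z_fitc = rng.normal(size=len(mice))

    rows = []
    for i, mouse in enumerate(mice):
        m = info[mouse]
        mu = fitc_log_mean + (treatment_shift if m.treatment != "CON" else 0.0)
        fitc_norm = float(np.exp(mu + fitc_log_sd * z_fitc[i]))
        weight = float(rng.normal(22.0, 2.0))
        rows.append({
            "mouse_id": mouse, "strain": m.strain, "treatment": m.treatment,
            "serum_fitc": fitc_norm * weight / 1e4, "body_weight": weight,
        })
    perm_df = pd.DataFrame(rows)

    genes = ("Ocln", "Cldn7", "ZO-1", "Muc-2")
    qrows = []
    for mouse in mice:
        m = info[mouse]
        for gene in genes:
            base = {"Ocln": 24.0, "Cldn7": 26.0, "ZO-1": 25.0,
                    "Muc-2": 22.0}[gene]
            effect = qpcr_effects.get((gene, m.strain, m.treatment), 0.0)
            ct_t = base - effect + float(rng.normal(0, 0.2))
            qrows.append({
                "sample_id": mouse, "strain": m.strain,
                "treatment": m.treatment, "target_gene": gene,
                "ct_target": ct_t,
                "ct_ref1": 18.0 + float(rng.normal(0, 0.15)),
                "ct_ref2": 20.0 + float(rng.normal(0, 0.15)),
            })
    qpcr_df = pd.DataFrame(qrows)
    truth = PlantedTruth(
        permeability_coupling=(coupling_taxon, coupling_rho)
        if coupling_taxon else None,
        qpcr_effects=dict(qpcr_effects),
    )
    return perm_df, qpcr_df, truth
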