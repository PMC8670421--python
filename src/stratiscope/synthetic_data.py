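"""Synthetic stratified-community metatranscriptome generator.

Emulates the study design the package targets: biological duplicates from
five depth layers sampled in two months, with a community of order-level
taxa whose transcriptional activity follows smooth (logistic) depth
profiles.  Every downstream stage has programmable ground truth:

* per-taxon depth-activity profiles (logistic midpoint/slope, month factor);
* per-taxon allocation of transcription across gene systems (CAZymes,
  peptidases, transporters, archaeal marker genes, everything else), with
  the CAZyme:peptidase log2 ratio following a programmed linear trajectory
  in depth;
* marker-gene folds relative to the single-copy reference radA;
* environmental covariates shaped like the fjord profiles (temperature and
  DOC decreasing, nitrate increasing, a subsurface chlorophyll maximum),
  including a depth-collinear block and below-detection NH4+ values.

Counts are drawn per sample as a Dirichlet-multinomial: the expected ORF
composition is perturbed once per replicate (Dirichlet, concentration
``dirichlet_concentration``) and counts are then multinomial at a lognormal
library size.  ORF sampling probability is allocation x length/1kb, so TPM
recovers the programmed allocation while raw-count shares include the
length weighting; :class:`SyntheticTruth` records both.

All generators are pure functions of (config, seed): the same config yields
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from stratiscope.io_model import UNCLASSIFIED, CountMatrix, StratiscopeError

# Independent RNG streams per generator stage (stable regardless of call order)
_STREAM_COUNTS = 11
_STREAM_ENV = 13
_STREAM_CAZY = 17
_STREAM_HITS = 19

GENE_SYSTEMS = ("CAZyme", "PEP", "TP", "marker", "other")

CAZY_FAMILIES = (
    "GH16", "GH13", "GH18", "GH3", "GH29", "GH92",
    "GT4", "GT2", "CBM50", "PL7", "CE4", "AA3",
)

# (MEROPS family, Pfam profile) pairs used for peptidase ORFs
MEROPS_FAMILIES = (
    ("S01A", "PF00089"), ("M01", "PF01433"), ("C01A", "PF00112"),
    ("M16", "PF00675"), ("S08A", "PF00082"), ("M23", "PF01551"),
)

# (TCDB family, TC number, Pfam profile) for transporter ORFs
TCDB_FAMILIES = (
    ("The ATP-binding Cassette (ABC) Superfamily", "3.A.1", "PF00005"),
    ("The Outer Membrane Receptor (OMR) Family", "1.B.14", "PF00593"),
    ("The Ion-translocating Microbial Rhodopsin (MR) Family", "3.E.1", "PF01036"),
    ("The Tripartite ATP-independent Periplasmic Transporter (TRAP-T) Family", "2.A.56", "PF03480"),
    ("The Solute:Sodium Symporter (SSS) Family", "2.A.21", "PF00474"),
    ("The General Bacterial Porin (GBP) Family", "1.B.1", "PF00267"),
)

#: Profiles whose TCDB mapping is known-bad upstream and corrected by the
#: shipped override table (ammonium channel and chloride channel).
AMT_PROFILE = "PF00909"
CLC_PROFILE = "PF00654"


@dataclass
class TaxonProfile:
    """Depth-activity and gene-system allocation for one order-level taxon.

    ``depth_midpoint_m``/``depth_slope`` parameterize a logistic activity
    profile (positive slope: activity rises with depth); ``september_factor``
    multiplies activity in September.  ``cazpep_intercept``/``cazpep_slope``
    program the log2(CAZyme/PEP) allocation trajectory as intercept +
    slope * depth_m.
    """

    name: str
    domain: str
    phylum: str
    class_: str
    activity_base: float = 1.0
    depth_midpoint_m: float = 40.0
    depth_slope: float = 0.0          # per metre
    september_factor: float = 1.0
    degradation_frac: float = 0.14    # CAZyme + PEP share of transcription
    tp_frac: float = 0.20
    marker_frac: float = 0.0
    cazpep_intercept: float = 0.0     # log2 units at 0 m
    cazpep_slope: float = 0.0         # log2 units per metre

    def activity(self, depth_m: float, month: str) -> float:
        z = self.depth_slope * (depth_m - self.depth_midpoint_m)
        sig = 1.0 / (1.0 + np.exp(-z))
        a = self.activity_base * (0.15 + 0.85 * sig)
        if month == "September":
            a *= self.september_factor
        return float(a)

    def cazpep_log2(self, depth_m: float) -> float:
        return self.cazpep_intercept + self.cazpep_slope * depth_m

    def system_fracs(self, depth_m: float) -> dict[str, float]:
        """Allocation fractions over gene systems at a given depth (sum to 1)."""
        r = 2.0 ** self.cazpep_log2(depth_m)
        caz = self.degradation_frac * r / (1.0 + r)
        pep = self.degradation_frac / (1.0 + r)
        other = 1.0 - self.degradation_frac - self.tp_frac - self.marker_frac
        return {
            "CAZyme": caz,
            "PEP": pep,
            "TP": self.tp_frac,
            "marker": self.marker_frac,
            "other": other,
        }


def default_taxa() -> list[TaxonProfile]:
    """Focal orders of a stratified fjord community (names are labels only).

    Surface-leaning photo/heterotrophs, depth-leaning nitrifiers, and a flat
    oligotroph; the ammonia-oxidizing archaeon carries the marker genes.
    The Flavobacteriales CAZyme:PEP trajectory runs from +1 (5 m) to -2
    (100 m) in log2 units.
    """
    return [
        TaxonProfile("Nitrosopumilales", "Archaea", "Thaumarchaeota", "Nitrososphaeria",
                     activity_base=1.0, depth_midpoint_m=30, depth_slope=0.12,
                     september_factor=1.15, degradation_frac=0.06, tp_frac=0.22,
                     marker_frac=0.06, cazpep_intercept=-1.2, cazpep_slope=-0.008),
        TaxonProfile("Pelagibacterales", "Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     activity_base=0.9, depth_midpoint_m=50, depth_slope=0.01,
                     september_factor=1.0, degradation_frac=0.10, tp_frac=0.25,
                     cazpep_intercept=-0.5, cazpep_slope=-0.004),
        TaxonProfile("Rhodobacterales", "Bacteria", "Proteobacteria", "Alphaproteobacteria",
                     activity_base=0.55, depth_midpoint_m=40, depth_slope=-0.06,
                     september_factor=1.1, degradation_frac=0.14, tp_frac=0.20,
                     cazpep_intercept=0.8, cazpep_slope=-0.02),
        TaxonProfile("Flavobacteriales", "Bacteria", "Bacteroidetes", "Flavobacteriia",
                     activity_base=0.7, depth_midpoint_m=30, depth_slope=-0.10,
                     september_factor=0.9, degradation_frac=0.18, tp_frac=0.12,
                     cazpep_intercept=1.1578947, cazpep_slope=-0.0315789),
        TaxonProfile("Cellvibrionales", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     activity_base=0.45, depth_midpoint_m=25, depth_slope=-0.12,
                     september_factor=0.85, degradation_frac=0.16, tp_frac=0.14,
                     cazpep_intercept=1.3, cazpep_slope=-0.01),
        TaxonProfile("Alteromonadales", "Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     activity_base=0.5, depth_midpoint_m=45, depth_slope=0.07,
                     september_factor=1.1, degradation_frac=0.12, tp_frac=0.22,
                     cazpep_intercept=0.0, cazpep_slope=-0.012),
        TaxonProfile("Synechococcales", "Bacteria", "Cyanobacteria", "Cyanophyceae",
                     activity_base=0.8, depth_midpoint_m=20, depth_slope=-0.15,
                     september_factor=1.25, degradation_frac=0.10, tp_frac=0.24,
                     cazpep_intercept=0.5, cazpep_slope=-0.015),
        TaxonProfile("Planctomycetales", "Bacteria", "Planctomycetes", "Planctomycetia",
                     activity_base=0.35, depth_midpoint_m=50, depth_slope=0.03,
                     september_factor=1.0, degradation_frac=0.14, tp_frac=0.14,
                     cazpep_intercept=0.3, cazpep_slope=-0.01),
        TaxonProfile("Nitrospinales", "Bacteria", "Nitrospinae", "Nitrospinia",
                     activity_base=0.3, depth_midpoint_m=50, depth_slope=0.10,
                     september_factor=1.0, degradation_frac=0.10, tp_frac=0.20,
                     cazpep_intercept=-0.3, cazpep_slope=-0.006),
    ]


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic dataset.

    Defaults reproduce the study conditions: 9 orders x 5 depths x 2 months
    x 2 replicates, mean library size 2e5.
    """

    taxa: list[TaxonProfile] = field(default_factory=default_taxa)
    orfs_per_taxon: int = 60
    depths_m: tuple = (5, 15, 50, 75, 100)
    months: tuple = ("July", "September")
    replicates: int = 2
    library_size_mean: float = 2e5
    library_size_sd_log: float = 0.2
    #: Dirichlet concentration for replicate-level overdispersion; chosen so
    #: dominant-group shares scatter by a few percent between duplicates.
    dirichlet_concentration: float = 2e4
    orf_length_mean_bp: float = 900.0
    orf_length_sd_log: float = 0.25
    marker_orf_length_bp: int = 1000
    amoa_rada_fold: float = 4.0
    hcd_rada_fold: float = 2.0
    amt_tp_share: float = 0.7         # share of archaeal TP allocation on the Amt ORF
    # ORFs per taxon by system (remainder is "other")
    n_cazyme_orfs: int = 12
    n_pep_orfs: int = 12
    n_tp_orfs: int = 12
    # fraction of non-prokaryotic "contaminant" ORFs appended to the tables
    n_eukaryote_orfs: int = 30
    n_unclassified_orfs: int = 15
    n_rrna_overlap_orfs: int = 10
    # environment
    env_noise_sd: float = 0.03
    nh4_detection_limit: float = 0.2
    env_duplicate_of: str | None = None  # add an exact copy of a covariate
    # CAZyme prediction-table knobs
    n_boundary_orfs: int = 3
    n_conflict_orfs: int = 3
    single_tool_lowq_prob: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if len(self.taxa) < 2:
            raise StratiscopeError("need at least 2 taxa")
        if len(self.depths_m) < 2:
            raise StratiscopeError("need at least 2 depths")
        if self.dirichlet_concentration <= 0 or self.library_size_sd_log <= 0:
            raise StratiscopeError("dispersions must be > 0")
        if self.replicates < 1:
            raise StratiscopeError("need at least 1 replicate")
        for t in self.taxa:
            fr = t.system_fracs(self.depths_m[0])
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise StratiscopeError(f"system fractions of {t.name} do not sum to 1")
            if min(fr.values()) < -1e-12 or fr["other"] <= 0:
                raise StratiscopeError(f"negative allocation fraction for {t.name}")
        n_sys = self.n_cazyme_orfs + self.n_pep_orfs + self.n_tp_orfs + 3
        if self.orfs_per_taxon < n_sys:
            raise StratiscopeError("orfs_per_taxon too small for the system layout")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taxa"] = [dataclasses.asdict(t) for t in self.taxa]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "taxa" in d:
            d["taxa"] = [TaxonProfile(**t) for t in d["taxa"]]
        for key in ("depths_m", "months"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated dataset."""

    #: one row per (taxon, sample): expected raw-count share of the library
    taxon_share: pd.DataFrame
    #: one row per (taxon|community, depth, month, ratio_type): true log2 ratio
    log_ratios: pd.DataFrame
    #: programmed marker folds relative to radA
    marker_folds: dict
    #: expected per-ORF library composition (ORF x sample probabilities)
    library_composition: pd.DataFrame
    #: per-ORF ground-truth functional role: taxon, system, family, marker
    orf_roles: pd.DataFrame
    #: per-sample stratum labels for clustering recovery
    sample_strata: pd.DataFrame

    def validate(self) -> None:
        sums = self.taxon_share.groupby("sample_id")["expected_share"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise StratiscopeError("taxon shares do not sum to 1 per sample")
        col = self.library_composition.sum(axis=0)
        if not np.allclose(col, 1.0, atol=1e-9):
            raise StratiscopeError("library composition does not sum to 1 per sample")


class SyntheticDataset(NamedTuple):
    counts: CountMatrix
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# ORF layout
# ---------------------------------------------------------------------------

def _build_orf_roles(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every prokaryotic ORF a taxon, gene system, family and weight.

    Within-system ORF weights are a fixed draw (Dirichlet alpha=2) so that
    composition is uneven but reproducible; marker ORFs are one per gene.
    """
    rows = []
    for t in config.taxa:
        is_archaeon = t.domain == "Archaea"
        layout: list[tuple[str, str, str]] = []  # (system, family, marker)
        for i in range(config.n_cazyme_orfs):
            layout.append(("CAZyme", CAZY_FAMILIES[i % len(CAZY_FAMILIES)], ""))
        for i in range(config.n_pep_orfs):
            layout.append(("PEP", MEROPS_FAMILIES[i % len(MEROPS_FAMILIES)][0], ""))
        for i in range(config.n_tp_orfs):
            if is_archaeon and i == 0:
                layout.append(("TP", "The Ammonium Channel Transporter (Amt) Family", "amt"))
            elif is_archaeon and i == 1:
                layout.append(("TP", "The Chloride Carrier/Channel (ClC) Family", ""))
            else:
                layout.append(("TP", TCDB_FAMILIES[i % len(TCDB_FAMILIES)][0], ""))
        if is_archaeon:
            layout += [("marker", "radA", "radA"), ("marker", "amoA", "amoA"),
                       ("marker", "hcd", "hcd")]
        n_other = config.orfs_per_taxon - len(layout)
        layout += [("other", "", "")] * n_other
        for j, (system, fam, marker) in enumerate(layout):
            rows.append((f"{t.name}_{j:03d}", t.name, system, fam, marker))
    roles = pd.DataFrame(rows, columns=["orf_id", "taxon", "system", "family", "marker"])

    # within-system relative weights (sum to 1 per taxon x system)
    weights = np.zeros(len(roles))
    for (taxon, system), grp in roles.groupby(["taxon", "system"], sort=False):
        idx = grp.index.to_numpy()
        if system == "marker":
            cfg = {"radA": 1.0, "amoA": 0.0, "hcd": 0.0}
            cfg["amoA"] = config.amoa_rada_fold
            cfg["hcd"] = config.hcd_rada_fold
            w = np.array([cfg[m] for m in grp["marker"]])
        elif system == "TP" and (grp["marker"] == "amt").any():
            w = rng.dirichlet(np.full(len(idx) - 1, 2.0)) * (1 - config.amt_tp_share)
            w = np.insert(w, 0, config.amt_tp_share)
        else:
            w = rng.dirichlet(np.full(len(idx), 2.0))
        weights[idx] = w / w.sum()
    roles["within_system_weight"] = weights

    # lengths: lognormal, marker genes at a fixed characteristic length
    mu = np.log(config.orf_length_mean_bp) - config.orf_length_sd_log**2 / 2
    lens = np.maximum(
        100, np.round(rng.lognormal(mu, config.orf_length_sd_log, len(roles)))
    ).astype(int)
    lens[roles["marker"].isin(["radA", "amoA", "hcd"])] = config.marker_orf_length_bp
    roles["length_bp"] = lens
    return roles


def _extra_orfs(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Eukaryote / unclassified / rRNA-overlap ORFs exercising the input filters."""
    rows = []
    for i in range(config.n_eukaryote_orfs):
        rows.append((f"euk_{i:03d}", "Eukaryota", False))
    for i in range(config.n_unclassified_orfs):
        rows.append((f"uncl_{i:03d}", UNCLASSIFIED, False))
    for i in range(config.n_rrna_overlap_orfs):
        rows.append((f"rrna_{i:03d}", "Bacteria", True))
    df = pd.DataFrame(rows, columns=["orf_id", "domain", "is_rrna_overlap"])
    mu = np.log(config.orf_length_mean_bp) - config.orf_length_sd_log**2 / 2
    df["length_bp"] = np.maximum(
        100, np.round(rng.lognormal(mu, config.orf_length_sd_log, len(df)))
    ).astype(int)
    # flat, small expected share of the library (~2% in total)
    df["weight"] = 0.02 / max(len(df), 1)
    return df


def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for month in config.months:
        for depth in config.depths_m:
            for rep in range(1, config.replicates + 1):
                rows.append((f"{month[:3]}_{int(depth):03d}m_r{rep}", depth, month, rep))
    return pd.DataFrame(rows, columns=["sample_id", "depth_m", "month", "replicate"])


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset (counts, taxonomy, metadata, truth)."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])

    roles = _build_orf_roles(config, rng)
    extra = _extra_orfs(config, rng)
    samples = _sample_table(config)
    taxa_by_name = {t.name: t for t in config.taxa}

    # expected per-ORF composition per sample: activity x allocation x weight,
    # length-weighted (count probability ~ molecules x length)
    n_orfs = len(roles) + len(extra)
    orf_ids = list(roles["orf_id"]) + list(extra["orf_id"])
    lengths = np.concatenate([roles["length_bp"].to_numpy(), extra["length_bp"].to_numpy()])
    comp = np.zeros((n_orfs, len(samples)))
    share_rows = []
    sys_frac_cache: dict[tuple[str, float], dict[str, float]] = {}
    for s_i, srow in samples.iterrows():
        depth, month = srow["depth_m"], srow["month"]
        act = np.array([taxa_by_name[n].activity(depth, month) for n in taxa_by_name])
        act = act / act.sum()
        act_by_taxon = dict(zip(taxa_by_name, act))
        alloc = np.empty(len(roles))
        for r_i, (taxon, system, w) in enumerate(
            zip(roles["taxon"], roles["system"], roles["within_system_weight"])
        ):
            key = (taxon, depth)
            if key not in sys_frac_cache:
                sys_frac_cache[key] = taxa_by_name[taxon].system_fracs(depth)
            alloc[r_i] = act_by_taxon[taxon] * sys_frac_cache[key][system] * w
        prok_total = 1.0 - extra["weight"].sum()
        full_alloc = np.concatenate([alloc * prok_total, extra["weight"].to_numpy()])
        p = full_alloc * lengths / 1000.0
        p /= p.sum()
        comp[:, s_i] = p
        prok_share = pd.Series(p[: len(roles)]).groupby(roles["taxon"].to_numpy()).sum()
        for taxon in taxa_by_name:
            share_rows.append(
                (taxon, srow["sample_id"], depth, month, srow["replicate"],
                 prok_share.get(taxon, 0.0))
            )
    # count-share truth includes the non-prokaryote tail; normalize over all ORFs
    taxon_share = pd.DataFrame(
        share_rows,
        columns=["taxon", "sample_id", "depth_m", "month", "replicate", "expected_share"],
    )
    # renormalize shares to prokaryote-only basis used downstream? No: shares
    # are of the whole library; add a pseudo-taxon for the non-prokaryote tail
    tail_rows = (
        taxon_share.drop_duplicates("sample_id")[
            ["sample_id", "depth_m", "month", "replicate"]
        ].assign(taxon="(non-prokaryote)")
    )
    tail_rows["expected_share"] = (
        1.0 - taxon_share.groupby("sample_id")["expected_share"].sum().loc[
            tail_rows["sample_id"]
        ].to_numpy()
    )
    taxon_share = pd.concat(
        [taxon_share, tail_rows[taxon_share.columns]], ignore_index=True
    )

    # draw counts: Dirichlet perturbation per sample, multinomial at lognormal N
    counts = np.zeros((n_orfs, len(samples)), dtype=np.int64)
    mu_n = np.log(config.library_size_mean) - config.library_size_sd_log**2 / 2
    for s_i in range(len(samples)):
        alpha = config.dirichlet_concentration * comp[:, s_i]
        p = _dirichlet_safe(rng, alpha)
        n = int(np.round(rng.lognormal(mu_n, config.library_size_sd_log)))
        counts[:, s_i] = rng.multinomial(n, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=orf_ids, columns=list(samples["sample_id"])),
        pd.Series(lengths, index=orf_ids, name="length_bp"),
    )

    taxonomy = _build_taxonomy(roles, extra, taxa_by_name)
    metadata = generate_environment(config.depths_m, config.months, config)
    truth = SyntheticTruth(
        taxon_share=taxon_share,
        log_ratios=_true_log_ratios(config, taxa_by_name),
        marker_folds={"amoA": config.amoa_rada_fold, "hcd": config.hcd_rada_fold},
        library_composition=pd.DataFrame(
            comp, index=orf_ids, columns=list(samples["sample_id"])
        ),
        orf_roles=roles,
        sample_strata=_strata(samples),
    )
    truth.validate()
    return SyntheticDataset(cm, taxonomy, metadata, truth)


def _dirichlet_safe(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw via gammas, tolerating very small alphas (sparse ORFs)."""
    g = rng.gamma(np.maximum(alpha, 1e-12), 1.0)
    tot = g.sum()
    if tot <= 0:  # pragma: no cover - astronomically unlikely
        g = alpha
        tot = g.sum()
    return g / tot


def _build_taxonomy(roles, extra, taxa_by_name) -> pd.DataFrame:
    rows = []
    for orf_id, taxon in zip(roles["orf_id"], roles["taxon"]):
        t = taxa_by_name[taxon]
        rows.append((orf_id, t.domain, t.phylum, t.class_, t.name,
                     UNCLASSIFIED, UNCLASSIFIED, False))
    for orf_id, domain, is_rrna in zip(
        extra["orf_id"], extra["domain"], extra["is_rrna_overlap"]
    ):
        rows.append((orf_id, domain, UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED,
                     UNCLASSIFIED, UNCLASSIFIED, bool(is_rrna)))
    df = pd.DataFrame(
        rows,
        columns=["orf_id", "domain", "phylum", "class", "order", "family",
                 "genus", "is_rrna_overlap"],
    )
    return df.set_index("orf_id", drop=False)


def _true_log_ratios(config, taxa_by_name) -> pd.DataFrame:
    """Programmed allocation log2 ratios per taxon and for the whole community."""
    rows = []
    for month in config.months:
        for depth in config.depths_m:
            acts = {n: t.activity(depth, month) for n, t in taxa_by_name.items()}
            tot_act = sum(acts.values())
            sums = {"CAZyme": 0.0, "PEP": 0.0, "TP": 0.0}
            for name, t in taxa_by_name.items():
                fr = t.system_fracs(depth)
                for a, b, rt in (("CAZyme", "PEP", "CAZyme/PEP"),
                                 ("CAZyme", "TP", "CAZyme/TP"),
                                 ("PEP", "TP", "PEP/TP")):
                    rows.append((name, depth, month, rt, np.log2(fr[a] / fr[b])))
                for s in sums:
                    sums[s] += acts[name] / tot_act * fr[s]
            for a, b, rt in (("CAZyme", "PEP", "CAZyme/PEP"),
                             ("CAZyme", "TP", "CAZyme/TP"),
                             ("PEP", "TP", "PEP/TP")):
                rows.append(("(community)", depth, month, rt, np.log2(sums[a] / sums[b])))
    return pd.DataFrame(
        rows, columns=["taxon", "depth_m", "month", "ratio_type", "true_log2"]
    )


def _strata(samples: pd.DataFrame) -> pd.DataFrame:
    out = samples[["sample_id", "depth_m", "month"]].copy()
    out["stratum_depth2"] = np.where(out["depth_m"] < 50, "surface", "deep")
    out["stratum_month_depth4"] = out["month"].str[:3] + "-" + out["stratum_depth2"]
    return out


# ---------------------------------------------------------------------------
# Environment generator
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def generate_environment(depths_m, months, config: SyntheticConfig) -> pd.DataFrame:
    """Metadata table with fjord-like covariate profiles.

    Temperature, oxygen and DOC decrease with depth; salinity, NO3-+NO2- and
    PO43- increase (the latter two near-collinear, exercising correlation/VIF
    selection); Chl a peaks at a subsurface maximum in July and at the
    surface in September; July NH4+ sits below the detection limit and is
    flagged ``nh4_below_detection`` for downstream substitution.  Replicates
    share one CTD cast, so covariates repeat across replicate pairs.
    Multiplicative lognormal noise ``env_noise_sd`` (0 gives exact monotone
    profiles).
    """
    rng = np.random.default_rng([config.seed, _STREAM_ENV])
    rows = []
    for month in months:
        for depth in depths_m:
            d = float(depth)
            july = month == "July"
            env = {
                "temperature_C": (16.0 if july else 15.5) - 8.5 * _sigmoid((d - 35) / 8.0),
                "salinity_PSU": (28.0 if july else 22.0)
                + ((36.0 if july else 36.0) - (28.0 if july else 22.0)) * _sigmoid((d - 30) / 15.0),
                "oxygen_ml_per_l": 5.0 - 3.5 * _sigmoid((d - 40) / 15.0),
                "chla_ug_per_l": (0.5 + 0.9 * np.exp(-(((d - 15) / 8.0) ** 2)))
                if july
                else (0.15 + 2.65 * np.exp(-((d / 12.0) ** 2))),
                "doc_uM": 170.0 * np.exp(-0.011 * d),
                "nh4_uM": 0.05 if july else 0.3 + 0.5 * np.exp(-(((d - 50) / 30.0) ** 2)),
                "no3no2_uM": 0.5 + 39.0 * _sigmoid((d - 45) / 12.0),
                "sio2_uM": 2.0 + 28.0 * _sigmoid((d - 50) / 15.0),
                "totN_uM": 35.0,
                "totP_uM": 0.5 + 0.4 * _sigmoid((d - 45) / 20.0),
            }
            # phosphate: affine in nitrate -> a deliberately collinear block
            env["po4_uM"] = 0.3 + 0.105 * env["no3no2_uM"]
            if config.env_noise_sd > 0:
                for k in env:
                    env[k] = float(env[k] * rng.lognormal(0.0, config.env_noise_sd))
            else:
                env = {k: float(v) for k, v in env.items()}
            below = env["nh4_uM"] < config.nh4_detection_limit
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{month[:3]}_{int(depth):03d}m_r{rep}",
                        "depth_m": d,
                        "month": month,
                        "replicate": rep,
                        **env,
                        "nh4_below_detection": bool(below),
                    }
                )
    meta = pd.DataFrame(rows)
    if config.env_duplicate_of:
        meta[f"{config.env_duplicate_of}_dup"] = meta[config.env_duplicate_of]
    return meta.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Functional-prediction fixtures
# ---------------------------------------------------------------------------

def generate_cazyme_predictions(
    roles: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Raw three-tool CAZyme prediction table for the CAZyme-bearing ORFs.

    Emits 1-3 tool records per ORF around configurable quality means.  The
    first ``n_boundary_orfs`` CAZyme ORFs get single-tool records with
    metrics exactly at the consensus thresholds (identity 50.0, coverage
    0.5, 10 hits, cycling); the next ``n_conflict_orfs`` get two tools
    voting for different families.  A fraction of ordinary single-tool
    records is drawn below threshold (true dropouts).
    """
    rng = np.random.default_rng([config.seed, _STREAM_CAZY])
    caz = roles.loc[roles["system"] == "CAZyme"].reset_index(drop=True)
    rows = []

    def alignment_row(orf, fam, ident):
        return dict(orf_id=orf, tool="alignment", family=fam,
                    percent_identity=round(float(ident), 1), coverage=np.nan,
                    hits=np.nan, frequency=np.nan)

    def profile_row(orf, fam, cov):
        return dict(orf_id=orf, tool="profile", family=fam, percent_identity=np.nan,
                    coverage=round(float(cov), 3), hits=np.nan, frequency=np.nan)

    def pattern_row(orf, fam, hits, freq):
        return dict(orf_id=orf, tool="pattern", family=fam, percent_identity=np.nan,
                    coverage=np.nan, hits=int(hits), frequency=round(float(freq), 3))

    makers = (
        lambda orf, fam: alignment_row(orf, fam, np.clip(rng.normal(80, 10), 30, 100)),
        lambda orf, fam: profile_row(orf, fam, np.clip(rng.normal(0.85, 0.08), 0.05, 1.0)),
        lambda orf, fam: pattern_row(orf, fam, max(1, rng.poisson(30)),
                                     rng.gamma(2.0, 0.5)),
    )
    boundary = (
        lambda orf, fam: alignment_row(orf, fam, 50.0),
        lambda orf, fam: profile_row(orf, fam, 0.5),
        lambda orf, fam: pattern_row(orf, fam, 10, 1.0),
    )
    for i, row in caz.iterrows():
        orf, fam = row["orf_id"], row["family"]
        if i < config.n_boundary_orfs:
            rows.append(boundary[i % 3](orf, fam))
        elif i < config.n_boundary_orfs + config.n_conflict_orfs:
            other = CAZY_FAMILIES[(CAZY_FAMILIES.index(fam) + 1) % len(CAZY_FAMILIES)]
            t1, t2 = rng.choice(3, size=2, replace=False)
            rows.append(makers[t1](orf, fam))
            rows.append(makers[t2](orf, other))
        else:
            n_tools = rng.choice([1, 2, 3], p=[0.2, 0.35, 0.45])
            tools = rng.choice(3, size=n_tools, replace=False)
            if n_tools == 1 and rng.random() < config.single_tool_lowq_prob:
                t = tools[0]
                if t == 0:
                    rows.append(alignment_row(orf, fam, rng.uniform(30, 49.9)))
                elif t == 1:
                    rows.append(profile_row(orf, fam, rng.uniform(0.05, 0.49)))
                else:
                    rows.append(pattern_row(orf, fam, rng.integers(1, 10),
                                            rng.gamma(2.0, 0.5)))
            else:
                for t in tools:
                    rows.append(makers[t](orf, fam))
    return pd.DataFrame(rows)


def generate_functional_hits(roles: pd.DataFrame, config: SyntheticConfig) -> dict:
    """Peptidase, transporter and marker hit tables plus the Pfam->MEROPS map.

    The archaeal ammonium-channel ORF is emitted with the Pfam profile whose
    upstream TCDB mapping is wrong (PF00909), and the chloride-channel ORF
    with PF00654 -- both must be corrected by the shipped override table.
    Marker decoys carry a failing gathering-score flag.
    """
    rng = np.random.default_rng([config.seed, _STREAM_HITS])
    fam_to_pfam = {fam: pfam for fam, pfam in MEROPS_FAMILIES}
    tcdb_by_family = {fam: (tc, pfam) for fam, tc, pfam in TCDB_FAMILIES}

    pep_rows = []
    for _, row in roles.loc[roles["system"] == "PEP"].iterrows():
        pfam = fam_to_pfam[row["family"]]
        score = float(np.round(rng.normal(150, 40), 1))
        pep_rows.append(dict(orf_id=row["orf_id"], pfam=pfam, score=max(score, 25.0)))
        if rng.random() < 0.2:  # secondary, lower-scoring domain of another family
            other = MEROPS_FAMILIES[rng.integers(len(MEROPS_FAMILIES))]
            pep_rows.append(dict(orf_id=row["orf_id"], pfam=other[1],
                                 score=float(np.round(rng.uniform(25, 60), 1))))
    # an unmapped decoy accession on a non-PEP ORF -> side report downstream
    other_orfs = roles.loc[roles["system"] == "other", "orf_id"]
    if len(other_orfs):
        pep_rows.append(dict(orf_id=other_orfs.iloc[0], pfam="PF99999", score=30.0))
    pep_hits = pd.DataFrame(pep_rows)
    merops_map = pd.DataFrame(
        [{"pfam": pfam, "merops_family": fam} for fam, pfam in MEROPS_FAMILIES]
    )

    tp_rows = []
    for _, row in roles.loc[roles["system"] == "TP"].iterrows():
        fam = row["family"]
        score = float(np.round(rng.normal(180, 50), 1))
        if row["marker"] == "amt":
            # wrong upstream mapping, fixed by the default override table
            tp_rows.append(dict(orf_id=row["orf_id"], profile=AMT_PROFILE,
                                tcdb_family="The Nitrate/Nitrite Porter (NNP) Family",
                                tc_number="2.A.1.8", score=max(score, 25.0), gathering_pass=True))
        elif fam.startswith("The Chloride"):
            tp_rows.append(dict(orf_id=row["orf_id"], profile=CLC_PROFILE,
                                tcdb_family="The Voltage-gated Ion Channel (VIC) Superfamily",
                                tc_number="1.A.1.13", score=max(score, 25.0), gathering_pass=True))
        else:
            tc, pfam = tcdb_by_family[fam]
            tp_rows.append(dict(orf_id=row["orf_id"], profile=pfam, tcdb_family=fam,
                                tc_number=tc + ".1", score=max(score, 25.0),
                                gathering_pass=True))
    tp_hits = pd.DataFrame(tp_rows)

    marker_rows = []
    for _, row in roles.loc[roles["marker"].isin(["radA", "amoA", "hcd", "amt"])].iterrows():
        marker_rows.append(dict(orf_id=row["orf_id"], marker=row["marker"],
                                score=float(np.round(rng.normal(250, 60), 1)),
                                gathering_pass=True))
    if len(other_orfs) > 1:  # decoy below the gathering threshold
        marker_rows.append(dict(orf_id=other_orfs.iloc[1], marker="amoA",
                                score=12.0, gathering_pass=False))
    marker_hits = pd.DataFrame(marker_rows)

    return {
        "pep_hits": pep_hits,
        "merops_map": merops_map,
        "tp_hits": tp_hits,
        "marker_hits": marker_hits,
    }
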