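"""End-to-end pipeline: read/generate -> filter -> annotate -> normalize ->
diversity / ordination / investment / markers, with a run manifest.

A run is fully described by a :class:`RunConfig`; identical configs produce
byte-identical outputs.  Every stochastic stage (SRS, RDA, PERMANOVA) draws
from its own explicit seed, validated before execution.  The manifest
records package version, seeds, input digests and the per-stage ORF funnel
(predicted -> rRNA-removed -> prokaryote subset -> abundance-filtered).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from stratiscope import __version__
from stratiscope.annotation import (
    assign_markers,
    classify_peptidases,
    classify_transporters,
    combine_assignments,
    consensus_cazyme,
)
from stratiscope.diversity import diversity_table, richness_anova
from stratiscope.investment import (
    investment_log_ratios,
    marker_log_ratios,
    marker_relative_abundance,
    system_totals,
    taxon_relative_transcription,
)
from stratiscope.io_model import (
    StratiscopeError,
    filter_rrna_overlaps,
    read_count_table,
    read_metadata,
    read_taxonomy,
    subset_prokaryotes,
    write_count_table,
    write_metadata,
    write_taxonomy,
)
from stratiscope.normalize import abundance_filter, hellinger, srs_normalize, tpm
from stratiscope.ordination import (
    hierarchical_clusters,
    permanova,
    rda,
    select_env_variables,
)
from stratiscope.synthetic_data import (
    SyntheticConfig,
    generate_cazyme_predictions,
    generate_dataset,
    generate_functional_hits,
)

ALL_ANALYSES = ("diversity", "ordination", "investment", "markers")
STOCHASTIC_STAGES = ("srs", "rda", "permanova")


@dataclass
class RunConfig:
    """One config to drive the whole pipeline."""

    synthetic: SyntheticConfig | None = None
    input_paths: dict = field(default_factory=dict)  # counts/taxonomy/metadata/...
    min_cpm: float = 5.0
    min_samples: int = 2
    strict_cpm: bool = False
    seeds: dict = field(default_factory=dict)        # per stochastic stage
    n_permutations: int = 199
    analyses: tuple = ALL_ANALYSES
    out_dir: str = "stratiscope_out"

    def validate(self) -> None:
        if self.synthetic is None and not self.input_paths:
            raise StratiscopeError("config needs either synthetic settings or input paths")
        for stage in STOCHASTIC_STAGES:
            if stage not in self.seeds:
                raise StratiscopeError(
                    f"stochastic stage {stage!r} has no seed in the config"
                )
        if self.input_paths:
            for key, p in self.input_paths.items():
                if not Path(p).exists():
                    raise StratiscopeError(f"input path for {key!r} does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses; returns the result bundle.

    All stage outputs are written as TSV under ``config.out_dir`` and also
    returned in-memory; the manifest lands in ``manifest.txt``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, object]] = [("stratiscope_version", __version__)]
    bundle: dict = {}

    # ------------------------------------------------------------------ input
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        cm, taxonomy, metadata = ds.counts, ds.taxonomy, ds.metadata
        roles = ds.truth.orf_roles
        predictions = generate_cazyme_predictions(roles, config.synthetic)
        hits = generate_functional_hits(roles, config.synthetic)
        bundle["truth"] = ds.truth
        manifest.append(("input", f"synthetic(seed={config.synthetic.seed})"))
        write_count_table(cm, out / "counts.tsv")
        write_taxonomy(taxonomy, out / "taxonomy.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        _write_tsv(predictions, out / "cazyme_predictions.tsv")
        for name, df in hits.items():
            _write_tsv(df, out / f"{name}.tsv")
    else:
        paths = config.input_paths
        cm = read_count_table(paths["counts"])
        taxonomy = read_taxonomy(paths["taxonomy"])
        metadata = read_metadata(paths["metadata"])
        predictions = pd.read_csv(paths["cazyme_predictions"], sep="\t")
        hits = {
            name: pd.read_csv(paths[name], sep="\t")
            for name in ("pep_hits", "merops_map", "tp_hits", "marker_hits")
        }
        for key in sorted(paths):
            manifest.append((f"input_digest:{key}", _digest(Path(paths[key]))))

    # ----------------------------------------------------------------- filter
    n_input = cm.shape[0]
    cm_rr, n_removed = filter_rrna_overlaps(cm, taxonomy)
    cm_prok = subset_prokaryotes(cm_rr, taxonomy)
    cm_filt = abundance_filter(
        cm_prok, min_cpm=config.min_cpm, min_samples=config.min_samples,
        strict=config.strict_cpm,
    )
    funnel = {
        "orfs_input": n_input,
        "orfs_rrna_removed": n_removed,
        "orfs_after_rrna_filter": cm_rr.shape[0],
        "orfs_prokaryote": cm_prok.shape[0],
        "orfs_abundance_filtered": cm_filt.shape[0],
    }
    manifest += list(funnel.items())
    bundle["funnel"] = funnel
    bundle["counts_filtered"] = cm_filt
    bundle["metadata"] = metadata
    write_count_table(cm_filt, out / "counts_filtered.tsv")

    # --------------------------------------------------------------- annotate
    asg_caz = consensus_cazyme(predictions)
    asg_pep, pep_unmapped = classify_peptidases(hits["pep_hits"], hits["merops_map"])
    asg_tp = classify_transporters(hits["tp_hits"])
    asg_mark = assign_markers(hits["marker_hits"])
    assignments = combine_assignments(asg_caz, asg_pep, asg_tp, asg_mark)
    # annotation applies to the analysis (filtered) ORF set
    assignments = assignments.loc[
        assignments["orf_id"].isin(set(cm_filt.orf_ids))
    ].reset_index(drop=True)
    bundle["assignments"] = assignments
    _write_tsv(assignments, out / "assignments.tsv")
    _write_tsv(pep_unmapped, out / "pep_unmapped.tsv")
    manifest.append(("assignments_total", len(assignments)))
    for system, grp in assignments.groupby("system"):
        manifest.append((f"assignments_{system}", len(grp)))

    # -------------------------------------------------------------- normalize
    hel = hellinger(cm_filt)
    tpm_m = tpm(cm_filt)
    srs = srs_normalize(cm_filt, "auto", seed=config.seeds["srs"])
    hel.write(out / "hellinger.tsv")
    tpm_m.write(out / "tpm.tsv")
    srs.write(out / "srs.tsv")

    subset_ids = {
        "all": list(cm_filt.orf_ids),
        "CAZyme": list(assignments.loc[assignments.system == "CAZyme", "orf_id"]),
        "PEP": list(assignments.loc[assignments.system == "PEP", "orf_id"]),
        "TP": list(assignments.loc[assignments.system == "TP", "orf_id"]),
    }

    # -------------------------------------------------------------- diversity
    if "diversity" in config.analyses:
        tables = []
        anovas = []
        for tag, ids in subset_ids.items():
            if len(ids) < 3:
                continue
            sub = cm_filt.subset_orfs(ids)
            sub_srs = srs_normalize(sub, "auto", seed=config.seeds["srs"])
            tab = diversity_table(sub_srs, subset_tag=tag)
            tables.append(tab)
            cmp_ = richness_anova(tab, metadata)
            anovas.append(
                {
                    "subset_tag": tag,
                    "f_statistic": cmp_.f_statistic,
                    "df_between": cmp_.df_between,
                    "df_within": cmp_.df_within,
                    "p_value": cmp_.p_value,
                }
            )
        bundle["diversity"] = pd.concat(tables, ignore_index=True)
        bundle["diversity_anova"] = pd.DataFrame(anovas)
        _write_tsv(bundle["diversity"], out / "diversity.tsv")
        _write_tsv(bundle["diversity_anova"], out / "diversity_anova.tsv")

    # -------------------------------------------------------------- ordination
    if "ordination" in config.analyses:
        selected = select_env_variables(metadata)
        ord_res, tests = rda(
            hel, metadata, selected,
            n_permutations=config.n_permutations, seed=config.seeds["rda"],
        )
        depth_groups = metadata.loc[hel.sample_ids, "depth_m"]
        perma = permanova(
            hel, depth_groups, n_permutations=config.n_permutations,
            seed=config.seeds["permanova"],
        )
        clus = hierarchical_clusters(hel)
        bundle.update(
            rda_result=ord_res, rda_tests=tests, permanova=perma, clustering=clus,
            selected_vars=selected,
        )
        _write_tsv(tests, out / "rda_tests.tsv")
        ord_res.sample_scores.to_csv(out / "rda_scores.tsv", sep="\t",
                                     lineterminator="\n", float_format="%.10g")
        _write_tsv(
            pd.DataFrame([perma]).drop(columns="groups"), out / "permanova.tsv"
        )
        pd.DataFrame(
            clus.linkage_matrix,
            columns=["child_a", "child_b", "height", "n_members"],
        ).to_csv(out / "linkage.tsv", sep="\t", index=False,
                 lineterminator="\n", float_format="%.10g")
        clus.labels.rename("cluster").to_frame().to_csv(
            out / "clusters.tsv", sep="\t", lineterminator="\n"
        )
        manifest += [
            ("rda_selected_vars", ",".join(selected)),
            ("rda_adjusted_r2", f"{ord_res.adjusted_r2:.6f}"),
            ("permanova_r2", f"{perma['r2']:.6f}"),
            ("clustering_chosen_k", clus.chosen_k),
        ]

    # -------------------------------------------------------------- investment
    if "investment" in config.analyses or "markers" in config.analyses:
        totals = system_totals(tpm_m, assignments, taxonomy)
        bundle["system_totals"] = totals
        _write_tsv(totals, out / "system_totals.tsv")
    if "investment" in config.analyses:
        rel = taxon_relative_transcription(cm_filt, taxonomy, rank="order")
        ratios = investment_log_ratios(totals, metadata)
        bundle["taxon_relative_transcription"] = rel
        bundle["investment_ratios"] = ratios
        _write_tsv(rel, out / "taxon_relative_transcription.tsv")
        _write_tsv(ratios, out / "investment_ratios.tsv")
    if "markers" in config.analyses:
        mabund = marker_relative_abundance(cm_filt, assignments, metadata)
        bundle["marker_abundance"] = mabund
        _write_tsv(mabund, out / "marker_abundance.tsv")
        if (mabund["marker"] == "radA").any():
            mratios = marker_log_ratios(mabund)
            bundle["marker_ratios"] = mratios
            _write_tsv(mratios, out / "marker_ratios.tsv")

    # ---------------------------------------------------------------- manifest
    for stage in STOCHASTIC_STAGES:
        manifest.append((f"seed_{stage}", config.seeds[stage]))
    with open(out / "manifest.txt", "w", encoding="utf-8") as fh:
        for key, val in manifest:
            fh.write(f"{key}\t{val}\n")
    bundle["manifest"] = dict(manifest)
    return bundle
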