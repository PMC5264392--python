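"""Orchestration of the comparative filtering battery.

``build_variants`` derives the named matrix variants (codon-position
subsets, amino-acid translation, conserved-block filtering, saturated-gene
removal, rate-tertile partitions, OV-sorted removal) from one supermatrix
and its gene partition map; ``run_battery`` runs tree inference, rival
trichotomy classification, bootstrap support, and stem-branch diagnostics
per variant; ``render_report`` writes the summary as TSV, JSON or
Markdown.  Every run embeds the configuration hash and the seed so the
report is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, PartitionMap, extract_codon_positions, \
    subset_genes, translate_codon_alignment
from .gblocks import gblocks_filter
from .ovremoval import apply_removal, detect_stopping_point, ov_sort, \
    removal_series
from .saturation import flag_saturated_genes, iss_test, ml_distance_matrix, \
    p_distance_matrix, patristic_matrix, saturation_regression
from .sites import classify_sites, compute_site_rate_table, tertile_partition
from .trees import bootstrap_support, classify_trichotomy, nj_tree, \
    parsimony_tree, stem_branch_report

VARIANT_NAMES = (
    "PCG", "PCG12", "AA",
    "GB-relaxed", "GB-default", "GB-strict",
    "Iss-keep", "Iss-drop", "slope-drop", "R2-drop",
    "OV-slow", "OV-medium", "OV-fast",
    "TIGER-slow", "TIGER-medium", "TIGER-fast",
    "OV-sorted",
)


class ConfigError(ValueError):
    pass


def _site_counts(aln: Alignment) -> dict:
    if aln.n_columns == 0:
        return {"width": 0, "variable": 0, "pis": 0}
    summ = classify_sites(aln).summary
    return {"width": summ["total"], "variable": summ["variable"],
            "pis": summ["parsimony_informative"]}


def _per_gene_regressions(aln: Alignment, pm: PartitionMap,
                          model: str = "GTR"):
    slopes, r2s = {}, {}
    for gene in pm.genes:
        sub, _ = subset_genes(aln, pm, {gene}, mode="keep")
        try:
            D = ml_distance_matrix(sub, model=model)
            tree = nj_tree(D.fillna(5.0))
            reg = saturation_regression(patristic_matrix(tree),
                                        p_distance_matrix(sub))
        except ValueError:
            continue
        slopes[gene] = reg.slope
        r2s[gene] = reg.R2
    return slopes, r2s


def build_variants(aln: Alignment, pm: PartitionMap,
                   config: dict | None = None):
    """Build the requested matrix variants.

    ``config`` keys: ``variants`` (list of names, default: all),
    ``iss`` (kwargs for the saturation test), ``flag`` (method/param for
    shoulder flagging), ``removal`` (increment / max_removed /
    jump_factor), ``tiger`` (bool: also compute TIGER tertiles),
    ``seed``.  Returns ``(variants, info)`` where ``variants`` maps name
    to :class:`Alignment` and ``info`` carries per-variant bookkeeping.
    """
    config = dict(config or {})
    requested = config.get("variants", list(VARIANT_NAMES))
    unknown = set(requested) - set(VARIANT_NAMES)
    if unknown:
        raise ConfigError(f"unknown variant name(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    variants: dict[str, Alignment] = {}
    info: dict[str, dict] = {}

    def add(name: str, variant: Alignment, **extra) -> None:
        variants[name] = variant
        info[name] = {**_site_counts(variant), **extra}

    if "PCG" in requested:
        add("PCG", aln)
    if "PCG12" in requested:
        add("PCG12", extract_codon_positions(aln, {1, 2}, pm))
    if "AA" in requested:
        add("AA", translate_codon_alignment(aln, pm=pm))
    for preset in ("relaxed", "default", "strict"):
        name = f"GB-{preset}"
        if name in requested:
            filtered, kept = gblocks_filter(aln, preset)
            add(name, filtered, kept_columns=len(kept))

    if "Iss-keep" in requested or "Iss-drop" in requested:
        iss_kw = dict(config.get("iss", {}))
        iss_kw.setdefault("seed", seed)
        saturated = set()
        per_gene = {}
        for gene in pm.genes:
            sub, _ = subset_genes(aln, pm, {gene}, mode="keep")
            st = iss_test(sub, **iss_kw)
            per_gene[gene] = st
            if st.saturated:
                saturated.add(gene)
        if "Iss-keep" in requested:
            kept, _ = subset_genes(aln, pm, saturated, mode="drop")
            add("Iss-keep", kept, n_genes_removed=len(saturated))
        if "Iss-drop" in requested:
            dropped, _ = subset_genes(aln, pm, saturated, mode="keep") \
                if saturated else (aln.take_columns([]), None)
            add("Iss-drop", dropped, n_genes=len(saturated))

    if "slope-drop" in requested or "R2-drop" in requested:
        flag_kw = dict(config.get("flag", {}))
        method = flag_kw.get("method", "valley")
        param = flag_kw.get("param", 15.0)
        slopes, r2s = _per_gene_regressions(aln, pm)
        if "slope-drop" in requested:
            flagged, cut = flag_saturated_genes(slopes, method, param)
            kept, _ = subset_genes(aln, pm, flagged, mode="drop")
            add("slope-drop", kept, n_genes_removed=len(flagged), cut=cut)
        if "R2-drop" in requested:
            flagged, cut = flag_saturated_genes(r2s, method, param)
            kept, _ = subset_genes(aln, pm, flagged, mode="drop")
            add("R2-drop", kept, n_genes_removed=len(flagged), cut=cut)

    rate_names = [n for n in requested
                  if n.startswith(("OV-", "TIGER-")) and n != "OV-sorted"]
    if rate_names:
        need_tiger = any(n.startswith("TIGER-") for n in rate_names)
        table = compute_site_rate_table(aln, tiger=need_tiger)
        for method in ("ov", "tiger"):
            prefix = "OV" if method == "ov" else "TIGER"
            wanted = [n for n in rate_names if n.startswith(prefix + "-")]
            if not wanted:
                continue
            slow, medium, fast, rep = tertile_partition(aln, table,
                                                        method=method)
            for name, part in zip((f"{prefix}-slow", f"{prefix}-medium",
                                   f"{prefix}-fast"), (slow, medium, fast)):
                if name in requested:
                    add(name, part)

    if "OV-sorted" in requested:
        rem = dict(config.get("removal", {}))
        increment = int(rem.get("increment", 250))
        max_removed = rem.get("max_removed")
        jump = float(rem.get("jump_factor", 3.0))
        sorted_aln, rank_map = ov_sort(aln)
        trace = removal_series(sorted_aln, increment=increment,
                               max_removed=max_removed,
                               model=rem.get("model", "GTR"))
        stop = detect_stopping_point(trace, jump_factor=jump)
        k_star = stop["k_star"]
        if k_star is None:
            add("OV-sorted", aln, k_removed=0, stopping=stop)
        else:
            add("OV-sorted", apply_removal(sorted_aln, k_star, rank_map),
                k_removed=k_star, stopping=stop)

    return variants, info


@dataclass
class BatteryReport:
    rows: list[dict] = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_battery(variants: dict[str, Alignment], info: dict,
                clades: dict[str, set], outgroup: set,
                config: dict | None = None, seed: int = 0) -> BatteryReport:
    """Infer, classify and support-measure every variant.

    ``config`` keys: ``method`` (nj / parsimony, default nj),
    ``distance_model``, ``n_bootstrap`` (0 disables), ``reference``
    (reference clade for stem ratios; default the last clade name).
    Variants whose molecule cannot be analysed by the chosen distance
    model fall back to p-distances.
    """
    config = dict(config or {})
    method = config.get("method", "nj")
    dmodel = config.get("distance_model", "GTR")
    n_boot = int(config.get("n_bootstrap", 0))
    reference = config.get("reference", list(clades)[-1])
    report = BatteryReport(config_hash=_config_hash(
        {**config, "variants": sorted(variants)}), seed=seed)
    for name, variant in variants.items():
        row = {"variant": name, **{k: v for k, v in info[name].items()
                                   if not isinstance(v, dict)}}
        if variant.n_columns == 0:
            row.update({"label": "skipped", "reason": "empty variant"})
            report.rows.append(row)
            continue
        try:
            if method == "parsimony" and variant.molecule == "nt":
                tree = parsimony_tree(variant)
            else:
                model = dmodel if variant.molecule == "nt" else "p"
                D = (p_distance_matrix(variant) if model == "p"
                     else ml_distance_matrix(variant, model=model))
                tree = nj_tree(D.fillna(5.0))
            row["label"] = classify_trichotomy(tree, clades, outgroup)
            stems = stem_branch_report(tree, clades, reference, outgroup)
            for cname, entry in stems.entries.items():
                row[f"stem_{cname}"] = entry["stem_length"]
                row[f"ratio_{cname}"] = entry["ratio"]
            if n_boot > 0:
                bs_model = dmodel if variant.molecule == "nt" else "p"
                if bs_model == "p":
                    support = _p_distance_bootstrap(
                        variant, clades, outgroup, n_boot, seed)
                else:
                    support = bootstrap_support(
                        variant, clades, outgroup,
                        infer=method if method in ("nj", "parsimony")
                        else "nj",
                        n_reps=n_boot, seed=seed, distance_model=bs_model)
                for lab, prop in support.proportions.items():
                    row[f"bs_{lab}"] = prop
        except ValueError as exc:
            row.update({"label": "skipped", "reason": str(exc)})
        report.rows.append(row)
    return report


def _p_distance_bootstrap(aln: Alignment, clades, outgroup, n_reps, seed):
    from .trees import HypothesisSupport
    rng = np.random.default_rng(seed)
    names = list(clades)
    counts = {f"{a}({b},{c})": 0 for a in names
              for b, c in [[n for n in names if n != a]]}
    counts["other"] = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_columns, aln.n_columns)
        rep = Alignment(aln.taxa, aln.matrix[:, cols], aln.molecule)
        tree = nj_tree(p_distance_matrix(rep).fillna(1.0))
        counts[classify_trichotomy(tree, clades, outgroup)] += 1
    return HypothesisSupport(counts=counts, n_reps=n_reps, seed=seed,
                             method="nj-p")


def render_report(report: BatteryReport, path, format: str = "tsv") -> None:
    """Write the battery report (stable column order)."""
    df = report.to_dataframe()
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {"config_hash": report.config_hash, "seed": report.seed,
                   "rows": report.rows}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
    elif format == "markdown":
        lines = [f"# Filtering battery report",
                 f"config hash: `{report.config_hash}`  seed: {report.seed}",
                 ""]
        if len(df):
            summary = df.groupby("label")["variant"].apply(
                lambda s: ", ".join(s)).reset_index()
            lines += ["| resolution | variants |", "| --- | --- |"]
            lines += [f"| {r.label} | {r.variant} |"
                      for r in summary.itertuples()]
            cols = list(df.columns)
            lines += ["", "| " + " | ".join(cols) + " |",
                      "| " + " | ".join("---" for _ in cols) + " |"]
            for _, r in df.iterrows():
                lines.append("| " + " | ".join(str(r[c]) for c in cols)
                             + " |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
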