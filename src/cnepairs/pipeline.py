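"""Stage chaining: simulate -> pairs -> ancestral -> metrics -> transposons
-> epigenetics -> som -> enrich, with TSV intermediates and a run manifest.

Stages communicate through TSV files with documented headers so every
intermediate is inspectable and re-runnable in isolation.  Reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (read_bed, read_gtf, read_hits, read_newick, read_track,
                 protein_coding_tss, GenomicInterval)
from .metrics import GenomeSizes, decile_groups, nrdd, nrtd, tss_distance, mean_conservation
from .pairs import (build_pairs, classify_conservation, classify_elements,
                    merge_and_filter, rbh_orthologs)
from .ancestral import PhyloModel, AncestorNotReconstructible
from .simulate import MAMMALS, SimConfig, simulate_all
from .transposons import (TransposonAnnotation, TRANSPOSON_CLASSES,
                          empirical_depletion_test, gain_loss,
                          transposon_density, transposon_free)
from .epigenetics import region_summaries, build_feature_matrix, coactivity_counts
from .som import KohonenSOM, unit_summaries, cluster_units
from .stats import group_unit_enrichment, odds_ratio, fisher_one_sided

logger = logging.getLogger(__name__)

STAGE_OUTPUTS = {
    "simulate": ["elements", "transposons", "tracks", "hits_forward.tsv",
                 "hits_reverse.tsv", "tree.nwk", "annotation.gtf", "genome.tsv"],
    "pairs": ["pairs.tsv", "orthologs.tsv"],
    "ancestral": ["ancestors.tsv"],
    "metrics": ["metrics.tsv"],
    "transposons": ["densities.tsv", "depletion.tsv", "gainloss.tsv"],
    "epigenetics": ["features.tsv", "coactivity.tsv"],
    "som": ["som_model.json", "assignments.tsv", "unit_summaries.tsv", "clusters.tsv"],
    "enrich": ["enrichment.tsv"],
}

_PRODUCER = {out: stage for stage, outs in STAGE_OUTPUTS.items() for out in outs}


class MissingStageInput(FileNotFoundError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        producer = _PRODUCER.get(path.name, "simulate")
        raise MissingStageInput(
            f"missing input {path.name}: run the `{producer}` stage first")
    return path


def _read_tsv(path: Path, required: tuple[str, ...] = ("pair_id",)) -> pd.DataFrame:
    _require(path)
    producer = _PRODUCER.get(path.name, "unknown")
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"corrupt {path.name} (from stage `{producer}`): {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"corrupt {path.name} (from stage `{producer}`): missing columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_genome_table(indir: Path) -> pd.DataFrame:
    return _read_tsv(Path(indir) / "genome.tsv",
                     required=("species", "chrom", "chrom_len", "genome_size"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_pairs(indir, outdir, focal: str = "human") -> pd.DataFrame:
    """Elements BED + GTF + hit tables -> pairs.tsv and orthologs.tsv."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_genome_table(indir)
    species = list(genome["species"])

    raw = [iv for iv, _n, _s in read_bed(_require(indir / "elements" / f"{focal}.bed"))]
    merged = merge_and_filter(raw)
    features = read_gtf(_require(indir / "annotation.gtf"))
    elements = classify_elements(merged, features)
    pairs = build_pairs(elements)

    hits_fwd = read_hits(_require(indir / "hits_forward.tsv"))
    hits_rev = read_hits(_require(indir / "hits_reverse.tsv"))
    query_intervals = {el.element_id: el.interval for el in elements}
    omap = rbh_orthologs(hits_fwd, hits_rev, query_intervals)
    pairs = classify_conservation(pairs, omap, species, focal=focal)

    rows, orows = [], []
    for p in pairs:
        row = [p.pair_id, p.chrom, p.left.interval.start, p.left.interval.end,
               p.right.interval.start, p.right.interval.end,
               p.left.category, p.right.category, p.d_h, p.conservation]
        row += [p.species_distance.get(sp, np.nan) for sp in species]
        rows.append(row)
        for sp in species:
            if sp == focal:
                lo = p.left.interval.midpoint
                hi = p.right.interval.midpoint
                orows.append([p.pair_id, sp, p.chrom, lo, hi])
                continue
            a = omap.get(p.left.element_id, {}).get(sp)
            b = omap.get(p.right.element_id, {}).get(sp)
            if a is None or b is None or a.chrom != b.chrom:
                continue
            lo, hi = sorted([a.midpoint, b.midpoint])
            orows.append([p.pair_id, sp, a.chrom, lo, hi])
    cols = (["pair_id", "chrom", "left_start", "left_end", "right_start",
             "right_end", "left_category", "right_category", "d_h",
             "conservation"] + [f"dist_{sp}" for sp in species])
    df = pd.DataFrame(rows, columns=cols)
    _write_tsv(df, outdir / "pairs.tsv")
    _write_tsv(pd.DataFrame(orows, columns=["pair_id", "species", "chrom",
                                            "span_start", "span_end"]),
               outdir / "orthologs.tsv")
    logger.info("pairs: %d pairs (%d mammalian-conserved)", len(df),
                int((df["conservation"].isin(["mammalian", "both"])).sum()))
    return df


def stage_ancestral(indir, outdir, seed: int = 0) -> pd.DataFrame:
    """pairs.tsv + tree + transposon BEDs -> ancestors.tsv (d_r, T_h, T_r)."""
    indir, outdir = Path(indir), Path(outdir)
    pairs = _read_tsv(outdir / "pairs.tsv")
    ortho = _read_tsv(outdir / "orthologs.tsv")
    tree = read_newick(_require(indir / "tree.nwk"))
    genome = read_genome_table(indir)
    species = list(genome["species"])
    mammals = [sp for sp in species if sp in MAMMALS]

    model = PhyloModel(tree, seed=seed)
    te = {
        sp: TransposonAnnotation.from_bed_records(
            read_bed(_require(indir / "transposons" / f"{sp}.bed")))
        for sp in species
    }

    span = {(r.pair_id, r.species): (r.chrom, int(r.span_start), int(r.span_end))
            for r in ortho.itertuples()}
    rows = []
    for r in pairs.itertuples():
        dists = {sp: float(getattr(r, f"dist_{sp}"))
                 for sp in mammals if np.isfinite(getattr(r, f"dist_{sp}"))}
        flags = []
        if "platypus" not in dists:
            d_r, n_tips = np.nan, len(dists)
            flags.append("no_platypus")
            T_h = {cls: np.nan for cls in TRANSPOSON_CLASSES}
            T_r = {cls: np.nan for cls in TRANSPOSON_CLASSES}
        else:
            try:
                d_r, n_tips = model.ml_ancestral_state(dists, ancestor_of=set(mammals))
            except AncestorNotReconstructible as exc:
                d_r, n_tips = np.nan, len(dists)
                flags.append(f"skipped:{exc}")
            T_obs = {cls: {} for cls in TRANSPOSON_CLASSES}
            for sp in mammals:
                key = (r.pair_id, sp)
                if key not in span:
                    continue
                chrom, lo, hi = span[key]
                if hi <= lo:
                    continue
                region = GenomicInterval(chrom, lo, hi)
                for cls in TRANSPOSON_CLASSES:
                    T_obs[cls][sp] = float(te[sp].covered(region, cls))
            T_h = {cls: T_obs[cls].get("human", np.nan) for cls in TRANSPOSON_CLASSES}
            T_r = {}
            for cls in TRANSPOSON_CLASSES:
                obs = T_obs[cls]
                if "platypus" not in obs or len(obs) < 2:
                    T_r[cls] = np.nan
                    continue
                est, _ = model.ml_ancestral_state(obs, ancestor_of=set(mammals))
                if est < 0:
                    est = 0.0
                    flags.append(f"clamped_{cls}")
                T_r[cls] = est
        rows.append([r.pair_id, d_r, n_tips, ";".join(flags) or "."]
                    + [T_h[c] for c in TRANSPOSON_CLASSES]
                    + [T_r[c] for c in TRANSPOSON_CLASSES])
    cols = (["pair_id", "d_r", "n_tips", "flags"]
            + [f"T_h_{c}" for c in TRANSPOSON_CLASSES]
            + [f"T_r_{c}" for c in TRANSPOSON_CLASSES])
    df = pd.DataFrame(rows, columns=cols)
    _write_tsv(df, outdir / "ancestors.tsv")
    return df


def stage_metrics(indir, outdir, focal: str = "human") -> pd.DataFrame:
    """nRDD + groups, nRTD per class, TSS distance, mean conservation."""
    indir, outdir = Path(indir), Path(outdir)
    pairs = _read_tsv(outdir / "pairs.tsv")
    anc = _read_tsv(outdir / "ancestors.tsv")
    genome = read_genome_table(indir)
    g_focal = float(genome.set_index("species").loc[focal, "genome_size"])
    sizes = GenomeSizes(G_h=g_focal)

    df = pairs.merge(anc, on="pair_id", how="left")
    ok = df["d_r"].notna() & (df["d_r"] > 0)
    df = df[ok].copy().reset_index(drop=True)
    df["nrdd"] = nrdd(df["d_h"].to_numpy(), df["d_r"].to_numpy(), sizes)
    df["nrdd_group"] = decile_groups(df["nrdd"].to_numpy(), df["pair_id"].to_numpy())
    for cls in TRANSPOSON_CLASSES:
        df[f"nrtd_{cls}"] = nrtd(df[f"T_h_{cls}"].fillna(0).to_numpy(),
                                 df[f"T_r_{cls}"].fillna(0).to_numpy(), sizes)

    tss = protein_coding_tss(read_gtf(_require(indir / "annotation.gtf")))
    score_path = indir / "scores.bedGraph"
    score_track = read_track(score_path, "na", "H3K27ac") if score_path.exists() else None
    tssd, cons_l, cons_r = [], [], []
    for r in df.itertuples():
        span_mid = (int(r.left_start) + int(r.right_end)) // 2
        tssd.append(tss_distance((r.chrom, span_mid), tss))
        if score_track is not None:
            cons_l.append(mean_conservation(
                GenomicInterval(r.chrom, int(r.left_start), int(r.left_end)), score_track))
            cons_r.append(mean_conservation(
                GenomicInterval(r.chrom, int(r.right_start), int(r.right_end)), score_track))
        else:
            cons_l.append(np.nan)
            cons_r.append(np.nan)
    df["tss_distance"] = tssd
    df["cons_left"] = cons_l
    df["cons_right"] = cons_r

    keep = (["pair_id", "d_h", "d_r", "nrdd", "nrdd_group"]
            + [f"nrtd_{c}" for c in TRANSPOSON_CLASSES]
            + ["tss_distance", "cons_left", "cons_right"])
    out = df[keep]
    _write_tsv(out, outdir / "metrics.tsv")
    return out


def stage_transposons(indir, outdir, n_rep: int = 1000, seed: int = 0,
                      focal: str = "human") -> None:
    """Densities per pair, the randomization depletion test, gain/loss calls."""
    indir, outdir = Path(indir), Path(outdir)
    pairs = _read_tsv(outdir / "pairs.tsv")
    anc = _read_tsv(outdir / "ancestors.tsv").set_index("pair_id")
    genome = read_genome_table(indir)
    chrom_len = {r.chrom: int(r.chrom_len) for r in genome.itertuples()
                 if r.species == focal}
    te = TransposonAnnotation.from_bed_records(
        read_bed(_require(indir / "transposons" / f"{focal}.bed")))

    dens_rows, gl_rows, regions = [], [], []
    for r in pairs.itertuples():
        lmid = (int(r.left_start) + int(r.left_end)) // 2
        rmid = (int(r.right_start) + int(r.right_end)) // 2
        region = GenomicInterval(r.chrom, lmid, rmid)
        regions.append(region)
        d = transposon_density(region, te, region_id=r.pair_id)
        dens_rows.append([r.pair_id, d.length]
                         + [d.density[c] for c in TRANSPOSON_CLASSES]
                         + [d.total_density])
        if r.pair_id in anc.index:
            arow = anc.loc[r.pair_id]
            T_h = {c: float(arow[f"T_h_{c}"]) for c in TRANSPOSON_CLASSES}
            T_r = {c: float(arow[f"T_r_{c}"]) for c in TRANSPOSON_CLASSES}
            if not any(np.isnan(list(T_h.values()))) and not any(np.isnan(list(T_r.values()))):
                labels = gain_loss(T_h, T_r)
                gl_rows.append([r.pair_id]
                               + [labels[c] for c in TRANSPOSON_CLASSES]
                               + [transposon_free(T_h, T_r)])
    _write_tsv(pd.DataFrame(
        dens_rows, columns=["pair_id", "length"]
        + [f"density_{c}" for c in TRANSPOSON_CLASSES] + ["density_total"]),
        outdir / "densities.tsv")
    _write_tsv(pd.DataFrame(
        gl_rows, columns=["pair_id"] + [f"call_{c}" for c in TRANSPOSON_CLASSES]
        + ["transposon_free"]), outdir / "gainloss.tsv")

    res = empirical_depletion_test(regions, chrom_len, te, n_rep=n_rep, seed=seed)
    dep = pd.DataFrame(
        [[k, v.direction, v.prop_significant, v.empirical_p,
          v.median_real, v.median_random, v.n_rep] for k, v in res.items()],
        columns=["class", "direction", "prop_significant", "empirical_p",
                 "median_real", "median_random", "n_rep"])
    _write_tsv(dep, outdir / "depletion.tsv")


def stage_epigenetics(indir, outdir, focal: str = "human") -> pd.DataFrame:
    """Region summaries -> feature matrix + H3K27ac/H3K27me3 coactivity tables."""
    indir, outdir = Path(indir), Path(outdir)
    pairs_df = _read_tsv(outdir / "pairs.tsv")
    metrics = _read_tsv(outdir / "metrics.tsv")
    analysis_ids = set(metrics["pair_id"])

    track_dir = _require(indir / "tracks")
    tracks = {}
    for path in sorted(track_dir.glob("*.bedGraph")):
        tissue, mark = path.stem.rsplit("_", 1)
        tracks[(tissue, mark)] = read_track(path, tissue, mark)
    tissues = sorted({t for t, _m in tracks})

    from .pairs import CNEPair, ConservedElement
    summaries = []
    for r in pairs_df.itertuples():
        if r.pair_id not in analysis_ids:
            continue
        left = ConservedElement(f"{r.pair_id}_L", GenomicInterval(
            r.chrom, int(r.left_start), int(r.left_end)), r.left_category)
        right = ConservedElement(f"{r.pair_id}_R", GenomicInterval(
            r.chrom, int(r.right_start), int(r.right_end)), r.right_category)
        summaries.append(region_summaries(CNEPair(r.pair_id, left, right), tracks))

    features = build_feature_matrix(summaries, tissues)
    features.insert(0, "pair_id", features.index)
    _write_tsv(features, outdir / "features.tsv")
    features = features.drop(columns="pair_id").set_index(pd.Index(features["pair_id"]))

    co_rows = []
    for tissue in tissues:
        for mark in ("H3K27ac", "H3K27me3"):
            (both, h_only), (l_only, neither) = coactivity_counts(summaries, tissue, mark)
            table = ((both, h_only), (l_only, neither))
            co_rows.append([tissue, mark, both, h_only, l_only, neither,
                            odds_ratio(table), fisher_one_sided(table)])
    _write_tsv(pd.DataFrame(co_rows, columns=[
        "tissue", "mark", "both", "h_only", "l_only", "neither",
        "odds_ratio", "p"]), outdir / "coactivity.tsv")
    return features


def stage_som(outdir, seed: int = 0, n_clusters: int = 4) -> pd.DataFrame:
    """features.tsv -> SOM model, unit assignments, unit summaries, clusters."""
    outdir = Path(outdir)
    features = _read_tsv(outdir / "features.tsv").set_index("pair_id")
    som = KohonenSOM(random_state=seed)
    som.fit(features.to_numpy())
    assignments = som.predict(features.to_numpy())

    model_blob = {
        "params": som.get_params(),
        "codebooks": [[round(float(v), 6) for v in row] for row in som.codebooks_],
        "quantization_error": round(som.quantization_error_, 6),
        "initial_quantization_error": round(som.initial_quantization_error_, 6),
    }
    (outdir / "som_model.json").write_text(json.dumps(model_blob, indent=1, sort_keys=True))

    usum = unit_summaries(features, assignments, som.n_units)
    clusters = cluster_units(usum, k=n_clusters)
    adf = pd.DataFrame({"pair_id": features.index, "unit": assignments})
    adf["cluster"] = [clusters.get(u, -1) for u in assignments]
    _write_tsv(adf, outdir / "assignments.tsv")
    _write_tsv(usum.reset_index(), outdir / "unit_summaries.tsv")
    _write_tsv(pd.DataFrame(sorted(clusters.items()), columns=["unit", "cluster"]),
               outdir / "clusters.tsv")
    return adf


def stage_enrich(outdir) -> pd.DataFrame:
    """Group x unit odds ratios, one-sided Fisher tests, BH-FDR."""
    outdir = Path(outdir)
    assignments = _read_tsv(outdir / "assignments.tsv")
    metrics = _read_tsv(outdir / "metrics.tsv")
    df = assignments.merge(metrics[["pair_id", "nrdd_group"]], on="pair_id")
    enr = group_unit_enrichment(df["nrdd_group"].to_numpy(), df["unit"].to_numpy())
    _write_tsv(enr, outdir / "enrichment.tsv")
    return enr


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: SimConfig, outdir, n_rep: int = 200) -> Path:
    """Simulate inputs and run every stage; write a run manifest.

    ``n_rep`` scales the randomization test for pipeline runs; the
    module-level default of 1,000 replicates applies when the stage is run
    on its own.
    """
    outdir = Path(outdir)
    indir = outdir / "inputs"
    simulate_all(config, indir)
    stage_pairs(indir, outdir, focal=config.focal)
    stage_ancestral(indir, outdir, seed=config.seed)
    stage_metrics(indir, outdir, focal=config.focal)
    stage_transposons(indir, outdir, n_rep=n_rep, seed=config.seed, focal=config.focal)
    stage_epigenetics(indir, outdir, focal=config.focal)
    stage_som(outdir, seed=config.seed)
    stage_enrich(outdir)

    cfg_bytes = (indir / "config.yaml").read_bytes()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "n_rep": n_rep,
        "stages": list(STAGE_OUTPUTS),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
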