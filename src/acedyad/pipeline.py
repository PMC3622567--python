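"""End-to-end orchestration: extract -> scan -> stats/consensus/orthologs/enrichment.

Reports are TSV-first: every table carries ``# key=value`` provenance
comments (tool version, config hash, promoter counts) so that numbers in a
report can always be traced to the exact configuration that produced them.
Plotting is deliberately optional and nothing downstream parses images.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import consensus as consensus_mod
from . import dyad_scan, enrichment, promoter_io, spacer_stats

log = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    """One species: either a genome FASTA + annotation, or ready promoters."""

    label: str
    fasta: str | None = None
    annotation: str | None = None
    format: str = "tsv"
    promoters: str | None = None


@dataclass
class PipelineConfig:
    species: list[SpeciesInput] = field(default_factory=list)
    motif: str = dyad_scan.DEFAULT_MOTIF
    controls: list[str] = field(default_factory=lambda: list(dyad_scan.CONTROL_MOTIFS))
    max_spacer: int = dyad_scan.DEFAULT_MAX_SPACER
    promoter_length: int = 1000
    mode: str = "all_pairs"
    pct_gc: float = 25.0
    pct_at: float = 40.0
    low_pct: float = 10.0
    high_pct: float = 90.0
    min_width: int = 6
    cutoff: float = enrichment.DEFAULT_CUTOFF
    alpha: float = enrichment.DEFAULT_ALPHA
    sidedness: str = "two_sided"
    consensus_species: str | None = None
    ortholog_table: str | None = None
    condition_manifest: str | None = None
    seed: int = 0
    out_dir: str = "acedyad_out"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        species = [SpeciesInput(**s) for s in raw.pop("species", [])]
        return cls(species=species, **raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    out_dir: Path
    paths: dict[str, Path]
    profiles: dict[str, dict[str, dyad_scan.SpacerFrequencyProfile]]
    outliers: dict[str, spacer_stats.PercentileOutliers]
    windows: dict[tuple[str, str], list[spacer_stats.CorrelationWindow]]
    consensi: dict[int, consensus_mod.ConsensusString]
    ortholog_correlations: pd.DataFrame | None
    screen: list[enrichment.ScreenRow] | None
    config: PipelineConfig


def _write_tsv(df: pd.DataFrame, path: Path, meta: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a report TSV, skipping provenance comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def _load_species(sp: SpeciesInput, cfg: PipelineConfig) -> promoter_io.PromoterSet:
    if sp.promoters:
        pset = promoter_io.read_promoters(sp.promoters)
        pset.species_label = sp.label
        return pset
    if not (sp.fasta and sp.annotation):
        raise ValueError(f"species {sp.label}: need promoters, or fasta + annotation")
    store = promoter_io.load_genome(sp.fasta)
    genes = promoter_io.load_annotation(sp.annotation, sp.format)
    return promoter_io.extract_upstream(
        store, genes, cfg.promoter_length, species_label=sp.label
    )


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Ortholog groups: header = species labels, one gene id per cell."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report tables.

    Any stage failure aborts with the stage name; files written so far in
    this run are removed so a partial report is never left behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"tool": "acedyad", "version": __version__, "config": config.digest(),
            "seed": config.seed}
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "extract"
        psets = {sp.label: _load_species(sp, config) for sp in config.species}
        if not psets:
            raise ValueError("no species configured")

        stage = "scan"
        panel_motifs = [config.motif] + list(config.controls)
        profiles: dict[str, dict[str, dyad_scan.SpacerFrequencyProfile]] = {}
        pools: dict[str, dyad_scan.SpacerPool] = {}
        hits: dict[str, list[dyad_scan.DyadHit]] = {}
        for label, pset in psets.items():
            profiles[label] = dyad_scan.control_panel(
                pset, panel_motifs, config.max_spacer, config.mode
            )
            _, pools[label] = dyad_scan.scan_set(
                pset, config.motif, config.max_spacer, config.mode
            )
            hits[label] = dyad_scan.scan_hits(
                pset, config.motif, config.max_spacer, config.mode
            )
            rows = []
            for m in panel_motifs:
                prof = profiles[label][m]
                dg = dyad_scan.distinct_gene_profile(
                    dyad_scan.scan_hits(pset, m, config.max_spacer, config.mode),
                    m, len(pset.entries), config.max_spacer, label,
                ) if m == config.motif else None
                for n in range(config.max_spacer + 1):
                    rows.append({
                        "motif": m, "N": n, "count": int(prof.counts[n]),
                        "per_1000": prof.per_thousand[n],
                        "distinct_genes": int(dg.counts[n]) if dg is not None else np.nan,
                    })
            p = out / f"{label}.profiles.tsv"
            _write_tsv(pd.DataFrame(rows), p, {**meta, "species": label,
                                               "n_promoters": len(pset.entries)})
            written.append(p)
            hp = out / f"{label}.hits.tsv"
            _write_tsv(
                pd.DataFrame(
                    [
                        {"gene_id": h.gene_id, "motif": h.motif, "N": h.spacer_length,
                         "offset": h.first_start, "spacer": h.spacer}
                        for h in hits[label]
                    ],
                    columns=["gene_id", "motif", "N", "offset", "spacer"],
                ),
                hp, {**meta, "species": label},
            )
            written.append(hp)

        stage = "outliers"
        outliers: dict[str, spacer_stats.PercentileOutliers] = {}
        for label in psets:
            prof = profiles[label][config.motif]
            o = spacer_stats.percentile_outliers(
                prof.counts, config.low_pct, config.high_pct
            )
            outliers[label] = o
            rows = [
                {"N": n, "count": int(prof.counts[n]),
                 "flag": "peak" if n in o.peaks else ("dip" if n in o.dips else "")}
                for n in range(config.max_spacer + 1)
            ]
            p = out / f"{label}.outliers.tsv"
            _write_tsv(pd.DataFrame(rows), p, {
                **meta, "species": label, "low_pct": o.low_pct, "high_pct": o.high_pct,
                "low_value": o.low_value, "high_value": o.high_value,
            })
            written.append(p)

        stage = "correlate"
        windows: dict[tuple[str, str], list[spacer_stats.CorrelationWindow]] = {}
        labels = list(psets)
        rows = []
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                ws = spacer_stats.window_correlations(
                    profiles[la][config.motif].counts,
                    profiles[lb][config.motif].counts,
                    config.min_width,
                )
                windows[(la, lb)] = ws
                best = spacer_stats.best_window_per_width(ws)
                for w in ws:
                    rows.append({
                        "species_a": la, "species_b": lb, "start_N": w.start_N,
                        "width": w.width, "r": w.r, "t": w.t, "p": w.p,
                        "best_for_width": best.get(w.width) is w,
                    })
        if rows:
            p = out / "correlations.tsv"
            _write_tsv(pd.DataFrame(rows), p, meta)
            written.append(p)

        stage = "consensus"
        cons_label = config.consensus_species or labels[0]
        consensi = consensus_mod.consensus_all(
            pools[cons_label], config.pct_gc, config.pct_at, config.max_spacer
        )
        pool = pools[cons_label]
        rows = [
            {"N": n, "consensus": c.text, "conserved_positions": c.conserved_positions,
             "n_spacers": len(pool[n])}
            for n, c in sorted(consensi.items())
        ]
        p = out / "consensus.tsv"
        _write_tsv(pd.DataFrame(rows), p, {
            **meta, "species": cons_label,
            "pct_gc": config.pct_gc, "pct_at": config.pct_at,
        })
        written.append(p)
        comp_rows = []
        for n in sorted(consensi):
            if n == 0 or not pool[n]:
                continue
            comp = consensus_mod.position_composition(pool[n])
            for pos in range(comp.N):
                col = comp.column(pos)
                for b in consensus_mod.BASES:
                    comp_rows.append({"N": n, "position": pos + 1, "base": b,
                                      "pct": col[b]})
        p = out / "composition.tsv"
        _write_tsv(pd.DataFrame(comp_rows, columns=["N", "position", "base", "pct"]),
                   p, {**meta, "species": cons_label})
        written.append(p)

        stage = "orthologs"
        ortho_df: pd.DataFrame | None = None
        if config.ortholog_table:
            table = read_ortholog_table(config.ortholog_table)
            per_gene = {
                label: dyad_scan.per_gene_counts(hits[label], config.max_spacer)
                for label in labels
            }
            sub = {}
            orows = []
            for label in table.columns:
                if label not in psets:
                    raise ValueError(f"ortholog table column {label!r} is not a species")
                ids = [g for g in table[label].dropna().tolist()]
                sub[label] = spacer_stats.subset_profile(
                    per_gene[label], ids, config.motif, config.max_spacer, label,
                    scanned_genes=set(psets[label].entries),
                )
                for n in range(config.max_spacer + 1):
                    orows.append({
                        "species": label, "N": n,
                        "count": int(sub[label].counts[n]),
                        "per_gene": sub[label].counts[n] / sub[label].n_promoters,
                    })
            p = out / "ortholog_profiles.tsv"
            _write_tsv(pd.DataFrame(orows), p, meta)
            written.append(p)
            crows = []
            slabels = list(sub)
            for i, la in enumerate(slabels):
                for lb in slabels[i + 1 :]:
                    r = spacer_stats.pearson_r(sub[la].counts, sub[lb].counts)
                    n = config.max_spacer + 1
                    t = spacer_stats.t_from_r(r, n)
                    crows.append({
                        "species_a": la, "species_b": lb, "r": r, "t": t,
                        "p": spacer_stats.p_from_t(t, n - 2), "n": n,
                    })
            ortho_df = pd.DataFrame(crows)
            p = out / "ortholog_correlations.tsv"
            _write_tsv(ortho_df, p, meta)
            written.append(p)

        stage = "enrich"
        screen: list[enrichment.ScreenRow] | None = None
        if config.condition_manifest:
            manifest = pd.read_csv(
                config.condition_manifest, sep="\t", comment="#", dtype=str
            )
            conditions = []
            target = manifest.get("species")
            for _, row in manifest.iterrows():
                label = row["species"] if target is not None else labels[0]
                universe = frozenset(psets[label].entries)
                genes = frozenset(g for g in read_gene_list(row["path"]) if g in universe)
                conditions.append(
                    (label, enrichment.RegulationSet(
                        row["condition"], row["direction"], genes, universe
                    ))
                )
            by_label: dict[str, list[enrichment.RegulationSet]] = {}
            for label, reg in conditions:
                by_label.setdefault(label, []).append(reg)
            screen = []
            for label, regs in by_label.items():
                panel = {
                    m: dyad_scan.genes_by_spacer(
                        dyad_scan.scan_hits(psets[label], m, config.max_spacer, config.mode),
                        config.max_spacer,
                    )
                    for m in panel_motifs
                }
                screen.extend(
                    enrichment.condition_screen(
                        regs, panel, config.motif, config.alpha, config.cutoff,
                        config.sidedness, config.max_spacer,
                    )
                )
            p = out / "enrichment.tsv"
            _write_tsv(enrichment.screen_to_frame(screen), p, meta)
            written.append(p)

        stage = "report"
        bundle = ReportBundle(
            out, {pp.name: pp for pp in written}, profiles, outliers, windows,
            consensi, ortho_df, screen, config,
        )
        p = out / "summary.txt"
        p.write_text(make_report(bundle))
        written.append(p)
        bundle.paths[p.name] = p
        return bundle
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def make_report(bundle: ReportBundle) -> str:
    """Plain-text summary: peaks, dips, best windows, significant conditions."""
    cfg = bundle.config
    lines = [
        f"acedyad {__version__} report (config {cfg.digest()})",
        f"motif {cfg.motif}, max spacer {cfg.max_spacer}, mode {cfg.mode}",
        "",
    ]
    for label, prof_by_motif in bundle.profiles.items():
        prof = prof_by_motif[cfg.motif]
        o = bundle.outliers[label]
        lines.append(
            f"[{label}] {prof.total} dyads over {prof.n_promoters} promoters "
            f"({prof.total * 1000.0 / prof.n_promoters:.1f} per 1000 promoters)"
        )
        lines.append(f"  peaks (>{o.high_pct:.0f}th pct): {sorted(o.peaks) or '-'}")
        lines.append(f"  dips  (<{o.low_pct:.0f}th pct): {sorted(o.dips) or '-'}")
    common = spacer_stats.common_peaks(bundle.outliers)
    lines.append(f"common peaks across species: {sorted(common) or '-'}")
    lines.append("")
    for (la, lb), ws in bundle.windows.items():
        if not ws:
            continue
        best = max(ws, key=lambda w: w.r)
        lines.append(
            f"best window {la} vs {lb}: N={best.start_N}-{best.end_N} "
            f"(r={best.r:.3f}, t={best.t:.3f}, p={best.p:.4f}, width={best.width})"
        )
    if bundle.ortholog_correlations is not None:
        lines.append("")
        for _, row in bundle.ortholog_correlations.iterrows():
            lines.append(
                f"ortholog profile {row['species_a']} vs {row['species_b']}: "
                f"r={row['r']:.4f} (p={row['p']:.4g}, n={int(row['n'])})"
            )
    if bundle.consensi:
        nonzero = [c for c in bundle.consensi.values() if c.N > 0]
        summary = consensus_mod.summarize_consensus(bundle.consensi)
        lines.append("")
        lines.append(
            f"consensus: {len(nonzero)} spacer lengths; first-position G in "
            f"{summary.fraction_first_G:.0%}, last-position C in "
            f"{summary.fraction_last_C:.0%} of consensi"
        )
    if bundle.screen is not None:
        lines.append("")
        sig = [r.condition for r in bundle.screen if r.significant]
        lines.append(f"conditions significant in Grubbs screen: {sig or '-'}")
    return "\n".join(lines) + "\n"
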