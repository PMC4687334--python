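"""Readers, writers, run configuration and the pipeline driver.

TSV is the canonical interchange format; a minimal sites-only VCF dialect is
accepted for SNP tables.  Every file written here starts with provenance
header lines (``# binqtl <version>``, config hash, seed) so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binmap import GENO_LETTERS, BinMap, bin_length_summary, binmap_from_observations
from .distortion import detect_sdrs, line_composition, scan_distortion
from .expansion import ExpansionResult, adjust_map, expected_expansion
from .genome import BreedingScheme, ConfigurationError, GenomeSpec, QtlEffect, SelectedLocus
from .linkmap import LinkageMap, build_map
from .qtl import ScanSettings, cim_scan
from .simulate import TruePopulation, simulate_observations, simulate_population
from .snpfilter import filter_candidates
from .tables import ObservationMatrix, snp_table_from_genome, validate_snp_table

logger = logging.getLogger(__name__)

__all__ = [
    "read_snp_table",
    "write_snp_table",
    "read_vcf_sites",
    "write_vcf_sites",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "RunConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.6g"


def _provenance(seed=None, config_hash=None) -> list[str]:
    lines = [f"# binqtl {__version__}"]
    if config_hash is not None:
        lines.append(f"# config_hash {config_hash}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_tsv(frame: pd.DataFrame, path, seed=None, config_hash=None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(seed, config_hash):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_snp_table(snps: pd.DataFrame, path, **prov) -> None:
    write_tsv(snps, path, **prov)


def read_snp_table(path) -> pd.DataFrame:
    p = str(path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return read_vcf_sites(path)
    return validate_snp_table(read_tsv(path))


def read_vcf_sites(path) -> pd.DataFrame:
    """Sites-only VCF -> SNP table (REF = parent-1 allele, first ALT =
    parent-2).  INFO keys DP, MQsites and the QUAL column populate the
    optional filter columns when present."""
    from pysam import VariantFile

    rows = []
    with VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            alt = rec.alts[0] if rec.alts else "."
            rows.append(
                {
                    "snp_id": rec.id or f"{rec.chrom}_{rec.pos}",
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam exposes the 1-based VCF POS
                    "allele_p1": rec.ref,
                    "allele_p2": alt,
                    "depth": rec.info.get("DP", np.nan),
                    "avg_mappable_sites": rec.info.get("MQsites", np.nan),
                    "novel_allele_quality": rec.qual if rec.qual is not None else np.nan,
                }
            )
    frame = pd.DataFrame(rows)
    for col in ("depth", "avg_mappable_sites", "novel_allele_quality"):
        if frame[col].isna().all():
            frame = frame.drop(columns=[col])
    return validate_snp_table(frame)


def write_vcf_sites(snps: pd.DataFrame, path, contig_lengths: dict[str, int] | None = None) -> None:
    """SNP table -> minimal sites-only VCF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=binqtl{__version__}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=MQsites,Number=1,Type=Float,Description="Average mappable sites">\n')
        chroms = dict.fromkeys(snps["chrom"])
        for c in chroms:
            length = (contig_lengths or {}).get(c, int(snps.loc[snps["chrom"] == c, "pos"].max()))
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in snps.iterrows():
            info = []
            if "depth" in snps.columns and not pd.isna(row.get("depth")):
                info.append(f"DP={int(row['depth'])}")
            if "avg_mappable_sites" in snps.columns and not pd.isna(row.get("avg_mappable_sites")):
                info.append(f"MQsites={row['avg_mappable_sites']:g}")
            qual = row.get("novel_allele_quality")
            qual_s = f"{qual:g}" if qual is not None and not pd.isna(qual) else "."
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['allele_p1']}\t"
                f"{row['allele_p2']}\t{qual_s}\tPASS\t{';'.join(info) or '.'}\n"
            )


def write_genotype_matrix(binmap: BinMap, path, **prov) -> None:
    write_tsv(binmap.genotype_frame(), path, index=True, **prov)


def read_genotype_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Genotype letters TSV -> (codes, line_ids, marker_ids)."""
    frame = read_tsv(path, index_col=0)
    letters = frame.to_numpy(dtype="U1")
    codes = np.searchsorted(GENO_LETTERS, letters).astype(np.int8)
    return codes, list(frame.index), list(frame.columns)


def write_linkage_map(map_: LinkageMap, path, **prov) -> None:
    write_tsv(map_.markers, path, **prov)


def read_linkage_map(path) -> LinkageMap:
    return LinkageMap(read_tsv(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_dict``)."""

    seed: int
    genome: GenomeSpec
    scheme: BreedingScheme
    qtls: list[QtlEffect] = field(default_factory=list)
    selection: list[SelectedLocus] = field(default_factory=list)
    residual_sd: float = 1.0
    coverage: float = 0.31
    error_rate: float = 0.01
    window_size: int = 15
    h: float = 0.7
    grid: int = 100_000
    lod_threshold: float = 9.0
    distortion_alpha: float = 0.01
    distortion_min_informative: int = 50
    sdr_min_run: int = 3
    scan: ScanSettings = field(default_factory=ScanSettings)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        try:
            genome = GenomeSpec.uniform(
                [(c["name"], c["length_bp"], c["length_cm"]) for c in cfg["genome"]["chromosomes"]],
                snps_per_chrom=cfg["genome"].get("snps_per_chrom"),
            )
            s = cfg.get("scheme", {})
            i_raw = s.get("i", 1)
            scheme = BreedingScheme(
                j=int(s.get("j", 12)),
                i=float("inf") if str(i_raw) == "inf" else float(i_raw),
                n_lines=int(s.get("n_lines", 200)),
                final_step=s.get("final_step", "DH"),
                n_census=s.get("n_census"),
            )
            qtls = [QtlEffect(**q) for q in cfg.get("qtls", [])]
            selection = [SelectedLocus(**sl) for sl in cfg.get("selection", [])]
            ob = cfg.get("observe", {})
            bm = cfg.get("binmap", {})
            lm = cfg.get("linkmap", {})
            dt = cfg.get("distortion", {})
            qt = cfg.get("qtl_scan", {})
            config = cls(
                seed=int(cfg.get("seed", 0)),
                genome=genome,
                scheme=scheme,
                qtls=qtls,
                selection=selection,
                residual_sd=float(cfg.get("residual_sd", 1.0)),
                coverage=float(ob.get("coverage", 0.31)),
                error_rate=float(ob.get("error_rate", 0.01)),
                window_size=int(bm.get("window_size", 15)),
                h=float(bm.get("h", 0.7)),
                grid=int(bm.get("grid", 100_000)),
                lod_threshold=float(lm.get("lod_threshold", 9.0)),
                distortion_alpha=float(dt.get("alpha", 0.01)),
                distortion_min_informative=int(dt.get("min_informative", 50)),
                sdr_min_run=int(dt.get("min_run", 3)),
                scan=ScanSettings(**qt),
                raw=cfg,
            )
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ConfigurationError):
                raise
            raise ConfigurationError(f"invalid configuration: {exc}") from exc
        # cross-field checks before any compute
        if config.window_size < 3:
            raise ConfigurationError("binmap.window_size must be >= 3")
        if not 0.5 < config.h <= 1.0:
            raise ConfigurationError("binmap.h must be in (0.5, 1]")
        if config.coverage < 0 or not (0 <= config.error_rate < 0.5):
            raise ConfigurationError("invalid observation model parameters")
        if config.grid < 1000:
            raise ConfigurationError("binmap.grid must be >= 1000 bp")
        return config

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def demo_config(seed: int = 1) -> dict:
    """Small fully synthetic end-to-end configuration."""
    return {
        "seed": seed,
        "genome": {
            "chromosomes": [
                {"name": "chr1", "length_bp": 10_000_000, "length_cm": 50.0},
                {"name": "chr2", "length_bp": 8_000_000, "length_cm": 40.0},
            ],
            "snps_per_chrom": 5000,
        },
        "scheme": {"j": 12, "i": 1, "n_lines": 100, "final_step": "DH"},
        "qtls": [{"chrom": "chr1", "pos_bp": 5_000_000, "a": 1.5, "trait": "trait"}],
        "residual_sd": 2.0,
        "observe": {"coverage": 0.31, "error_rate": 0.01},
        "qtl_scan": {"max_cofactors": 5},
    }


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the stages in dependency order and write all artifacts.

    simulate -> observe -> binmap -> linkmap -> expansion -> distortion ->
    qtl.  Returns a summary dict (also written as summary.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "config_hash": config.config_hash()}
    summary: dict = {"version": __version__, **prov, "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        result = fn()
        dt = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, dt)
        summary["stages"][name] = result
        return result

    snps = snp_table_from_genome(config.genome)
    pop: TruePopulation = simulate_population(
        config.genome, config.scheme, selection=config.selection, qtls=config.qtls,
        residual_sd=config.residual_sd, seed=config.seed,
    )
    write_tsv(pop.segments_frame(), out / "segments.tsv", **prov)
    if pop.phenotypes:
        write_tsv(pop.phenotype_frame(), out / "phenotypes.tsv", **prov)
    write_snp_table(snps, out / "snps.tsv", **prov)
    stage("simulate", lambda: {"n_lines": pop.n_lines, "n_snps": len(snps)})

    obs = simulate_observations(pop, snps, config.coverage, config.error_rate,
                                seed=config.seed + 1)
    write_tsv(obs.to_frame(), out / "observations.tsv", **prov)
    stage("observe", lambda: {"total_reads": obs.total_reads})

    chrom_lengths = {c.name: c.length_bp for c in config.genome.chromosomes}
    bm = binmap_from_observations(
        obs, chrom_lengths=chrom_lengths, grid=config.grid,
        window_size=config.window_size, h=config.h,
    )
    write_tsv(bm.bins[["chrom", "start", "end", "marker_id"]], out / "bins.tsv", **prov)
    write_genotype_matrix(bm, out / "bin_genotypes.tsv", **prov)
    write_tsv(bin_length_summary(bm), out / "bin_lengths.tsv", **prov)
    stage("binmap", lambda: {
        "n_bins": bm.n_bins,
        "n_breakpoints": len(bm.breakpoints or []),
    })

    lmap = build_map(bm, lod_threshold=config.lod_threshold)
    write_linkage_map(lmap, out / "linkage_map.tsv", **prov)
    stage("linkmap", lambda: {
        "n_groups": lmap.n_groups,
        "total_cm": round(lmap.total_cm, 1),
        "mean_spacing_cm": lmap.mean_spacing_cm(),
    })

    alpha = expected_expansion(config.scheme)
    adjusted = adjust_map(lmap, alpha)
    write_linkage_map(adjusted, out / "linkage_map_f2_adjusted.tsv", **prov)
    exp = ExpansionResult(alpha, lmap.total_cm, adjusted.total_cm)
    stage("expansion", lambda: {
        "alpha_expected": alpha,
        "observed_cm": round(exp.observed_length_cm, 1),
        "adjusted_cm": round(exp.adjusted_length_cm, 1),
        "alpha_observed": exp.alpha_observed,
    })

    records = scan_distortion(bm, alpha=config.distortion_alpha,
                              min_informative=config.distortion_min_informative)
    sdrs = detect_sdrs(records, min_run=config.sdr_min_run)
    comp = line_composition(bm)
    write_tsv(records, out / "distortion.tsv", **prov)
    write_tsv(pd.DataFrame([asdict(s) for s in sdrs]), out / "sdrs.tsv", **prov)
    write_tsv(comp, out / "line_composition.tsv", **prov)
    stage("distortion", lambda: {
        "n_significant": int(records["significant"].sum()),
        "pct_significant": round(100.0 * records["significant"].mean(), 2),
        "n_sdrs": len(sdrs),
    })

    if pop.phenotypes:
        qtl_frames = []
        for trait, y in pop.phenotypes.items():
            profile, recs = cim_scan(y, lmap, bm.genotypes,
                                     marker_ids=list(bm.bins["marker_id"]),
                                     settings=config.scan, trait=trait)
            write_tsv(profile, out / f"lod_profile_{trait}.tsv", **prov)
            qtl_frames.append(recs)
        qtl_records = pd.concat(qtl_frames, ignore_index=True)
        write_tsv(qtl_records, out / "qtl_records.tsv", **prov)
        stage("qtl", lambda: {"n_qtls": len(qtl_records)})

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
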