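"""End-to-end analysis: frequencies -> HWE -> EM haplotypes -> LD -> forensic.

Inter-stage exchange is full precision; display rounding (2-decimal
percents, 4-decimal parameters) is confined to the report writers here.
Given identical inputs and seeds, two runs produce byte-identical outputs
(run logs carry seeds and iteration counts but no wall-clock times).
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .allele_stats import allele_frequencies, locus_summary
from .datatypes import PopulationSample
from .em import EMConfig, apply_significance_filter, em_haplotype_frequencies, significant_summary
from .forensic import forensic_report
from .hwe import DEFAULT_MC_REPS, hwe_test
from .io import read_genotype_table, round_half_up, write_frequency_tables
from .ld import ld_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_report"]


@dataclass
class RunConfig:
    genotype_path: Path
    output_dir: Path
    loci: tuple[str, ...] | None = None  # default: all loci in the file
    em: EMConfig = field(default_factory=EMConfig)
    hwe_reps: int = DEFAULT_MC_REPS
    seed: int = 0
    percent_display: bool = True

    def __post_init__(self) -> None:
        self.genotype_path = Path(self.genotype_path)
        self.output_dir = Path(self.output_dir)
        if not self.genotype_path.exists():
            raise FileNotFoundError(f"genotype table not found: {self.genotype_path}")


def _fmt_pct(x: float) -> str:
    return f"{round_half_up(100 * x, 2):.2f}"


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            if exc[0] is None:
                logger.info("stage=%s elapsed=%.3fs", name, time.perf_counter() - self.t0)
            else:
                logger.error("stage=%s failed: %s", name, exc[1])
            return False

    return _Timer()


def run_full_report(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write one TSV per published-style table.

    Returns a map of artifact name -> written path.  Any stage error
    propagates with the stage name attached.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines = [f"hlapopgen {__version__}", f"seed={config.seed}"]

    with _stage("read"):
        sample = read_genotype_table(config.genotype_path)
    loci = config.loci or sample.loci
    log_lines.append(f"input={config.genotype_path.name} N={sample.n} loci={','.join(loci)}")

    with _stage("frequencies"):
        tables = {locus: allele_frequencies(sample, locus) for locus in loci}
        path = out / "allele_frequencies.tsv"
        write_frequency_tables(tables, path, percent=config.percent_display)
        artifacts["allele_frequencies"] = path
        for locus in loci:
            s = locus_summary(sample, locus)
            log_lines.append(
                f"locus={locus} n_alleles={s.n_alleles} HO={s.ho:.4f} HE={s.he_biased:.4f}"
            )

    with _stage("hwe"):
        rows = []
        for i, locus in enumerate(loci):
            res = hwe_test(sample, locus, reps=config.hwe_reps, seed=config.seed + i)
            rows.append(
                {
                    "locus": locus,
                    "p_value": f"{res.p_value:.4f}",
                    "method": res.method,
                    "se": "" if res.se is None else f"{res.se:.5f}",
                }
            )
            log_lines.append(f"hwe locus={locus} p={res.p_value:.4f} method={res.method}")
        path = out / "hwe.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        artifacts["hwe"] = path

    hap_tables = {}
    with _stage("haplotypes"):
        tuples = [t for t in itertools.combinations(loci, 2)]
        if len(loci) >= 3:
            tuples.append(tuple(loci))
        for t in tuples:
            table = em_haplotype_frequencies(sample, t, config.em)
            apply_significance_filter(table, sample.n)
            hap_tables[t] = table
            n_sig, cum = significant_summary(table)
            log_lines.append(
                f"em loci={','.join(t)} haplotypes={len(table.entries)} "
                f"significant={n_sig} cumulative={_fmt_pct(cum)}% "
                f"iterations={table.n_iterations} converged={table.converged}"
            )
            rows = [
                {
                    "haplotype": "-".join(h),
                    "frequency": _fmt_pct(f) if config.percent_display else repr(f),
                    "significant": int(table.significant[h]),
                }
                for h, f in sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))
                if f > 0
            ]
            path = out / f"haplotypes_{'_'.join(t)}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            artifacts[f"haplotypes_{'_'.join(t)}"] = path

    with _stage("ld"):
        for pair in itertools.combinations(loci, 2):
            records = ld_table(hap_tables[pair], tables[pair[0]], tables[pair[1]])
            rows = [
                {
                    "haplotype": "-".join(r.haplotype),
                    "HF": _fmt_pct(r.hf),
                    "ALD": _fmt_pct(r.d),
                    "MLD": _fmt_pct(r.dmax),
                    "RLD": f"{r.dprime:.4f}",
                }
                for r in records
            ]
            path = out / f"ld_{'_'.join(pair)}.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            artifacts[f"ld_{'_'.join(pair)}"] = path

    with _stage("forensic"):
        report = forensic_report(sample, loci)
        frows = [
            {
                "locus": r.locus,
                "HO": f"{r.ho:.4f}",
                "HE": f"{r.he_biased:.4f}",
                "PM": f"{r.pm:.4f}",
                "PD": f"{r.pd:.4f}",
                "PIC": f"{r.pic:.4f}",
                "PPE": f"{r.ppe_expected:.4f}",
            }
            for r in report.loci
        ]
        path = out / "forensic.tsv"
        pd.DataFrame(frows).to_csv(path, sep="\t", index=False)
        artifacts["forensic"] = path
        log_lines.append(
            f"combined CPM={report.cpm:.3e} CPD={report.cpd:.6f} CPE={report.cpe:.6f}"
        )

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
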