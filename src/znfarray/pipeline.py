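"""End-to-end orchestration: parse -> catalog -> divtest -> dotplot -> selection."""

from __future__ import annotations

import importlib.metadata
from dataclasses import asdict
from pathlib import Path

from . import catalog, diversity, dotplot, io
from .parser import parse_allele, repeat_table_rows, validate_array
from .selection import (
    build_codon_alignment,
    empirical_bayes_site_classes,
    fit_site_model,
    likelihood_ratio_test,
    sitewise_selection_test,
)
from .selection.models import NESTED_PAIRS


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _version() -> str:
    try:
        return importlib.metadata.version("znfarray")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute the enabled stages and write all outputs under ``outdir``.

    Returns the run log (also written as ``run_log.json``), which records
    the seed, package version and parameters needed to reproduce the run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": _version(),
        "config": asdict(config),
        "stages_completed": [],
        "outputs": [],
        "incomplete": True,
    }

    def emit(name: str):
        log["outputs"].append(name)
        return outdir / name

    alleles = []
    nt_table = aa_table = None
    spectrum = None
    stage = "setup"

    try:
        if "parse" in config.stages:
            stage = "parse"
            if not config.fasta or not config.groups:
                raise PipelineError(stage, "parse stage requires fasta and groups paths")
            sequences = io.read_grouped_fasta(config.fasta, config.groups, config.id_delimiter)
            rows = []
            kept = []
            excluded = []
            for rec in sequences:
                allele = parse_allele(
                    rec.seq_id,
                    rec.sequence,
                    sample_id=rec.sample_id,
                    group=rec.group,
                    repeat_length=config.repeat_length,
                    leading_truncated=config.leading_truncated,
                    translate=False,
                )
                report = validate_array(allele, config.repeat_length)
                if not report.usable_for_catalog:
                    excluded.append({"allele_id": rec.seq_id, "issues": len(report.issues)})
                    continue
                allele = parse_allele(
                    rec.seq_id,
                    rec.sequence,
                    sample_id=rec.sample_id,
                    group=rec.group,
                    repeat_length=config.repeat_length,
                    leading_truncated=config.leading_truncated,
                )
                kept.append((rec, allele))
                rows.extend(repeat_table_rows(allele))
            io.write_tsv(rows, emit("repeat_table.tsv"))
            if excluded:
                io.write_tsv(excluded, emit("excluded_alleles.tsv"))
            alleles = kept
            log["stages_completed"].append(stage)

        if "catalog" in config.stages:
            stage = "catalog"
            if not alleles:
                raise PipelineError(stage, "catalog stage requires parsed alleles")
            records = [rec for rec, _ in alleles]
            nt_table = catalog.collapse_to_nt_alleles(records)
            aa_table = catalog.collapse_to_aa_alleles(nt_table)
            nt_table.to_dataframe().to_csv(emit("nt_alleles.tsv"), sep="\t", index=False)
            aa_table.to_dataframe().to_csv(emit("aa_alleles.tsv"), sep="\t", index=False)
            sharing = catalog.cross_group_sharing(nt_table, aa_table)
            io.write_json(
                {"nt_shared": sharing.nt_shared, "aa_shared": sharing.aa_shared},
                emit("sharing.json"),
            )
            encoding = catalog.assign_repeat_letters([a for _, a in alleles])
            io.write_tsv(
                [
                    {"allele_id": aid, "encoding": "-".join(syms)}
                    for aid, syms in sorted(encoding.symbols.items())
                ],
                emit("letter_encoding.tsv"),
            )
            io.write_tsv(
                [{"symbol": s, "nt_seq": nt} for s, nt in sorted(encoding.symbol_to_nt.items())],
                emit("letter_legend.tsv"),
            )
            io.write_fasta(
                ((r.allele_id, r.sequence) for r in nt_table.rows), emit("alleles.fasta")
            )
            repeats = [r.aa_seq for _, a in alleles for r in a.full_repeats]
            if repeats and len({len(r) for r in repeats}) == 1:
                site_report = catalog.find_polymorphic_sites(repeats)
                io.write_json(
                    {"columns": site_report.columns, "n_sites": site_report.n_sites},
                    emit("polymorphic_sites.json"),
                )
            log["stages_completed"].append(stage)

        if "divtest" in config.stages:
            stage = "divtest"
            if config.spectrum:
                spectrum = io.read_spectrum_table(config.spectrum)
            elif nt_table is not None:
                counts: dict[str, dict[str, int]] = {}
                for rec, _ in alleles:
                    lab = next(r.allele_id for r in nt_table.rows if r.sequence == rec.sequence.upper())
                    counts.setdefault(rec.group, {}).setdefault(lab, 0)
                    counts[rec.group][lab] += 1
                spectrum = diversity.GroupedAlleleSpectrum.from_counts(counts)
            else:
                raise PipelineError(stage, "divtest stage requires a spectrum or catalogued alleles")
            results = []
            if len(spectrum.groups) == 2:
                kinds = [diversity.TWO_GROUP, diversity.MULTI_GROUP]
            else:
                kinds = [diversity.MULTI_GROUP]
            for kind in kinds:
                res = diversity.permutation_test(
                    spectrum, kind, n_permutations=config.n_permutations, seed=config.seed
                )
                results.append(
                    {
                        "statistic_kind": kind,
                        "observed": res.observed_statistic,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "seed": res.seed,
                        "smaller_group": res.smaller_group or "",
                    }
                )
            io.write_tsv(results, emit("divtest.tsv"))
            log["stages_completed"].append(stage)

        if "dotplot" in config.stages:
            stage = "dotplot"
            if nt_table is None or not nt_table.rows:
                raise PipelineError(stage, "dotplot stage requires catalogued alleles")
            top = nt_table.rows[0]
            params = dotplot.DotplotParams(config.window, config.mismatch_limit)
            dp = dotplot.self_dotplot(top.sequence, params)
            io.write_matrix_tsv(dp.matrix, emit(f"dotplot_{top.allele_id}.tsv"))
            log["stages_completed"].append(stage)

        if "selection" in config.stages:
            stage = "selection"
            if not alleles:
                raise PipelineError(stage, "selection stage requires parsed alleles")
            aln = build_codon_alignment([a for _, a in alleles])
            if aln.n_taxa < 3:
                raise PipelineError(stage, f"only {aln.n_taxa} distinct repeats; need >= 3")
            fits = {}
            for model in config.models:
                fits[model] = fit_site_model(
                    aln,
                    model=model,
                    codon_freq_model=config.codon_freq_model,
                    n_restarts=config.n_restarts,
                    seed=config.seed,
                )
            io.write_tsv(
                [
                    {
                        "model": f.model,
                        "lnL": f.lnL,
                        "kappa": f.kappa,
                        "proportions": ",".join(f"{p:.4f}" for p in f.proportions),
                        "omegas": ",".join(f"{w:.4f}" for w in f.omegas),
                        "converged": int(f.converged),
                    }
                    for f in fits.values()
                ],
                emit("selection_fits.tsv"),
            )
            lrt_rows = []
            for (null_m, alt_m), _df in NESTED_PAIRS.items():
                if null_m in fits and alt_m in fits:
                    r = likelihood_ratio_test(fits[null_m], fits[alt_m])
                    lrt_rows.append(
                        {
                            "null": r.null_model,
                            "alt": r.alt_model,
                            "two_delta_l": r.two_delta_l,
                            "df": r.df,
                            "p_value": r.p_value,
                        }
                    )
            if lrt_rows:
                io.write_tsv(lrt_rows, emit("selection_lrt.tsv"))
            if "M2a" in fits:
                post = empirical_bayes_site_classes(fits["M2a"], aln)
                io.write_tsv(
                    [
                        {
                            "site": i,
                            "p_selected": post.p_selected[i],
                            "post_mean_omega": post.post_mean_omega[i],
                            "post_sd_omega": post.post_sd_omega[i],
                        }
                        for i in range(post.n_sites)
                    ],
                    emit("site_posteriors.tsv"),
                )
            sw = sitewise_selection_test(
                aln,
                codon_freq_model=config.codon_freq_model,
                freq_incorporation=config.freq_incorporation,
                correction=config.correction,
                seed=config.seed,
            )
            io.write_tsv(
                [
                    {
                        "site": i,
                        "omega": "" if sw.invariant[i] else f"{sw.omegas[i]:.4f}",
                        "statistic": sw.statistics[i],
                        "p_value": sw.p_values[i],
                        "significant_05": int(sw.significant_05[i]),
                        "significant_01": int(sw.significant_01[i]),
                        "invariant": int(sw.invariant[i]),
                    }
                    for i in range(sw.n_sites)
                ],
                emit("sitewise.tsv"),
            )
            log["stages_completed"].append(stage)

    except PipelineError:
        io.write_json(log, outdir / "run_log.json")
        raise
    except Exception as exc:  # stage-tagged abort; partial outputs stay marked incomplete
        io.write_json(log, outdir / "run_log.json")
        raise PipelineError(stage, str(exc)) from exc

    log["incomplete"] = False
    io.write_json(log, outdir / "run_log.json")
    return log
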