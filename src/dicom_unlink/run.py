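"""End-to-end pipeline: extract -> scan -> group -> plan -> apply.

This is the programmatic equivalent of one run of the tool; the command-line
interface is a thin wrapper over :func:`run`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .archive import extract_archives
from .plan import RemapOptions, build_plan, plan_summary
from .rewrite import ChangeReport, apply_plan
from .scan import group_by_series, normalize_modalities, scan_directory
from .uids import UidGenerator

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "EXIT_OK", "EXIT_NO_FILES", "EXIT_FAILURES", "run"]

EXIT_OK = 0
EXIT_FAILURES = 1
EXIT_NO_FILES = 3


@dataclass
class RunConfig:
    """Everything one invocation needs."""

    input_dir: Path
    options: RemapOptions = field(default_factory=RemapOptions)
    modalities: tuple[str, ...] = ()  # user tokens: CT / MR / PET; empty = all
    unzip: bool = False
    unzip_delete: bool = False
    output_dir: Path | None = None
    dry_run: bool = False
    recurse: bool = True
    uid_root: str = ""
    seed: int | None = None
    report_path: Path | None = None


@dataclass
class RunResult:
    exit_status: int
    report: ChangeReport | None
    summary: str
    n_series: int = 0
    n_files: int = 0


def run(config: RunConfig) -> RunResult:
    """Execute one full pass; never raises for per-file problems.

    Exit status 0 means every in-scope file was rewritten; a distinct status
    flags an empty scope, and any per-file failure makes the run nonzero
    while still producing the report.
    """
    if config.unzip:
        extraction = extract_archives(config.input_dir, delete_after=config.unzip_delete)
        log.info(
            "unzip: %d archive(s), %d file(s) extracted",
            extraction.archives_found,
            extraction.files_extracted,
        )

    modality_filter = normalize_modalities(config.modalities)
    records = scan_directory(
        config.input_dir, modality_filter=modality_filter, recurse=config.recurse
    )
    groups = group_by_series(records)
    if not groups:
        return RunResult(EXIT_NO_FILES, None, "no DICOM files in scope")

    gen = UidGenerator(root=config.uid_root, seed=config.seed)
    plan = build_plan(groups, config.options, uid_source=gen)
    summary = plan_summary(plan, groups)
    n_files = sum(len(g) for g in groups)

    if config.dry_run:
        return RunResult(EXIT_OK, None, summary, n_series=len(groups), n_files=n_files)

    done = {"n": 0}

    def progress(entry) -> None:
        done["n"] += 1
        log.info("[%d/%d] %s", done["n"], n_files, entry.path)

    report = apply_plan(
        plan,
        records,
        output_dir=config.output_dir,
        input_root=config.input_dir if config.output_dir else None,
        progress_sink=progress,
    )
    if config.report_path is not None:
        Path(config.report_path).write_text(report.to_json())

    status = EXIT_OK if report.files_failed == 0 else EXIT_FAILURES
    return RunResult(status, report, summary, n_series=len(groups), n_files=n_files)
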