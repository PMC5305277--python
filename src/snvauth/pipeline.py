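"""End-to-end authentication runs: VCF in, verdict and report out."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .authenticate import compare_to_panel, compare_to_reference, screen_contaminant, verdict
from .filtering import FilterConfig, SnvProfile, build_profile
from .types import ComparisonResult, PanelResult, ScreenResult, Verdict
from .variant_io import NoProfileError, read_panel, read_reference_profile, read_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_authentication", "EXIT_AUTHENTICATED",
           "EXIT_NOT_AUTHENTICATED", "EXIT_INDETERMINATE", "EXIT_INPUT_ERROR"]

EXIT_AUTHENTICATED = 0
EXIT_NOT_AUTHENTICATED = 2
EXIT_INDETERMINATE = 3
EXIT_INPUT_ERROR = 4


def _checksum(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one authentication run computed, reproducibly.

    Each number in the rendered report is derivable from the logged
    config echo plus the checksummed inputs.
    """

    sample_id: str
    profile: SnvProfile
    comparison: ComparisonResult
    verdict: Verdict
    screen: Optional[ScreenResult] = None
    panel: Optional[PanelResult] = None
    version: str = __version__
    config_echo: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        if self.comparison.n_overlap == 0:
            return EXIT_INDETERMINATE
        return EXIT_AUTHENTICATED if self.verdict.authenticated else EXIT_NOT_AUTHENTICATED

    def to_dict(self) -> dict:
        d = {
            "version": self.version,
            "sample_id": self.sample_id,
            "n_input_calls": self.profile.n_input_calls,
            "n_profile_snvs": len(self.profile),
            "filter_log": dict(self.profile.filter_log),
            "comparison": self.comparison.to_dict(),
            "authenticated": self.verdict.authenticated,
            "verdict_notes": list(self.verdict.notes),
            "config": self.config_echo,
            "input_checksums": self.input_checksums,
        }
        if self.screen is not None:
            d["screen"] = {
                "summary": self.screen.summary,
                "status": self.screen.status,
                "warning": self.screen.warning,
                **self.screen.result.to_dict(),
            }
        if self.panel is not None:
            d["panel"] = {
                "summary": self.panel.summary,
                "n_loci": self.panel.n_loci,
                "n_overlap": self.panel.n_overlap,
                "n_match": self.panel.n_match,
            }
        return d


def run_authentication(
    vcf: Union[str, Path],
    profile_file: Union[str, Path],
    cell_line: str,
    contaminant_file: Optional[Union[str, Path]] = None,
    contaminant_cell_line: str = "HELA",
    panel_file: Optional[Union[str, Path]] = None,
    config: FilterConfig = FilterConfig(),
    sample_id: Optional[str] = None,
    sample: Optional[str] = None,
    concordance_threshold: float = 0.90,
    min_overlap: int = 25,
) -> RunReport:
    """Build the filtered SNV profile and run every requested comparison.

    Raises :class:`NoProfileError` if the reference file has no rows for
    the requested cell line; an empty VCF yields an indeterminate report,
    not an error.
    """
    calls = read_vcf(vcf, include_hom_ref=config.keep_hom_ref, sample=sample)
    sample_id = sample_id or Path(vcf).stem
    snv_profile = build_profile(calls, config, sample_id=sample_id)
    logger.info("profile %s: %d of %d calls pass filtering (%s)",
                sample_id, len(snv_profile), snv_profile.n_input_calls,
                snv_profile.filter_log)

    reference = read_reference_profile(profile_file, cell_line)
    if len(snv_profile):
        comparison = compare_to_reference(snv_profile, reference)
    else:
        comparison = ComparisonResult(
            sample_id=sample_id, reference_cell_line=cell_line,
            n_reference=len(reference), n_overlap=0, n_match=0, n_mismatch=0,
        )
    v = verdict(comparison, concordance_threshold=concordance_threshold,
                min_overlap=min_overlap)

    screen = None
    if contaminant_file is not None:
        contaminant = read_reference_profile(contaminant_file, contaminant_cell_line)
        screen = screen_contaminant(snv_profile, contaminant)

    panel_result = None
    if panel_file is not None:
        loci = read_panel(panel_file, cell_line=cell_line)
        panel_result = compare_to_panel(snv_profile, loci)

    checksums = {"vcf": _checksum(vcf), "profile": _checksum(profile_file)}
    if contaminant_file is not None:
        checksums["contaminant"] = _checksum(contaminant_file)
    if panel_file is not None:
        checksums["panel"] = _checksum(panel_file)

    return RunReport(
        sample_id=sample_id,
        profile=snv_profile,
        comparison=comparison,
        verdict=v,
        screen=screen,
        panel=panel_result,
        config_echo={
            **{k: getattr(config, k) for k in FilterConfig.__dataclass_fields__},
            "concordance_threshold": concordance_threshold,
            "min_overlap": min_overlap,
        },
        input_checksums=checksums,
    )
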