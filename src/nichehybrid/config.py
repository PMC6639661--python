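"""Analysis configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the niche/neutral/hybrid classification.

    Parameters
    ----------
    k
        Modal/rare abundance threshold, a fraction in (0, 1). An OTU is modal
        when its relative abundance reaches ``k`` (default 5%).
    threshold_mode
        Denominator convention for ``k``: ``"fraction_of_total"`` (relative
        abundance, default) or ``"fraction_of_max"`` (fraction of the most
        abundant OTU's count).
    n_null
        Null mode count for Silverman's test; the null hypothesis is that the
        nearest-distance density has at most ``n_null`` modes.
    n_boot
        Smoothed-bootstrap replicates for the Silverman p-value.
    alpha_sig
        Significance level; p below it calls the community HYBRID.
    niche_mode_factor
        For unimodal samples, the call is NICHE when the primary mode sits
        below ``niche_mode_factor`` times the neutral expectation 3(L-M)/(4L),
        otherwise NEUTRAL.
    min_rare
        Minimum number of rare OTUs required before a classification is
        attempted; smaller samples are flagged instead of called.
    grid_size
        Number of evaluation points for the kernel density estimate.
    bandwidth_tol
        Relative tolerance of the critical-bandwidth bisection.
    seed
        Seed for the smoothed bootstrap; mandatory on the command line.
    """

    k: float = 0.05
    threshold_mode: str = "fraction_of_total"
    n_null: int = 1
    n_boot: int = 999
    alpha_sig: float = 0.05
    niche_mode_factor: float = 0.5
    min_rare: int = 50
    grid_size: int = 512
    bandwidth_tol: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"k must lie in (0, 1), got {self.k}")
        if self.threshold_mode not in ("fraction_of_total", "fraction_of_max"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.n_boot < 1 or self.n_null < 1:
            raise ValueError("n_boot and n_null must be positive")
        if not 0.0 < self.alpha_sig < 1.0:
            raise ValueError("alpha_sig must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
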