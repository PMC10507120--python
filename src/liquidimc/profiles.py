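"""Cell-type expression profiles and cohort configuration for the generator.

A :class:`CellTypeProfile` encodes what the ion-count generator assumes about
one cell population: per-marker mean ion counts (counts/pixel over the cell
footprint), nuclear geometry, and its abundance within a sample. The disease
plasma-cell profile differs from the precursor/normal one only on a declared
subset of elevated markers by a declared fold change, so that the downstream
precursor-vs-disease comparison tests a known effect structure.

Mean ion counts are in raw detector counts per pixel per ablation; values of
2-30 counts/pixel for positive markers against a diffuse background of
0.1-0.5 counts/pixel are typical of antibody staining read out at 1 um^2
resolution, and are the regime the quantification stage is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from liquidimc.panel import PanelDefinition, default_panel

__all__ = [
    "CellTypeProfile",
    "SampleConfig",
    "CohortConfig",
    "default_profiles",
    "apply_fold_change",
    "DEFAULT_ELEVATED_MARKERS",
    "CONDITIONS",
]

CONDITIONS = ("precursor", "disease", "normal")

#: Markers elevated on overt-disease plasma cells in the default generator.
DEFAULT_ELEVATED_MARKERS = ("BCMA", "ICAM3", "CD221")

#: Default fold change applied to the elevated-marker subset on disease PCs.
DEFAULT_FOLD_CHANGE = 3.0


@dataclass(frozen=True)
class CellTypeProfile:
    """Generator model of one cell population.

    Parameters
    ----------
    name
        Population name (``PC_normal``, ``PC_disease``, ``T_cell``, ...).
    marker_means
        Mean ion counts per pixel for each expressed marker; markers absent
        from the mapping are at background level. All means must be >= 0.
    nuclear_radius, nuclear_radius_sd
        Mean and SD of the nuclear radius in pixels.
    eccentricity, eccentricity_sd
        Mean and SD of the nuclear eccentricity (0 = circle).
    abundance
        Fraction of cells of this type within a sample; per-sample
        abundances are normalized to sum to 1.
    """

    name: str
    marker_means: dict[str, float] = field(default_factory=dict)
    nuclear_radius: float = 6.0
    nuclear_radius_sd: float = 0.8
    eccentricity: float = 0.25
    eccentricity_sd: float = 0.1
    abundance: float = 0.0

    def __post_init__(self) -> None:
        bad = {m: v for m, v in self.marker_means.items() if v < 0}
        if bad:
            raise ValueError(f"negative marker means in profile {self.name!r}: {bad}")
        if self.nuclear_radius <= 0:
            raise ValueError("nuclear_radius must be positive")
        if not 0 <= self.abundance <= 1:
            raise ValueError("abundance must lie in [0, 1]")

    def validate_against(self, panel: PanelDefinition) -> None:
        """Raise ``ValueError`` naming any marker not present in *panel*."""
        unknown = [m for m in self.marker_means if m not in panel.markers]
        if unknown:
            raise ValueError(
                f"profile {self.name!r} references markers not in the panel: {unknown}"
            )


def _intercalator_means() -> dict[str, float]:
    # DNA intercalators stain every nucleus; counts/pixel over the nucleus.
    return {"DNA1": 25.0, "DNA2": 25.0}


def default_profiles(
    elevated_markers: tuple[str, ...] = DEFAULT_ELEVATED_MARKERS,
    fold_change: float = DEFAULT_FOLD_CHANGE,
) -> dict[str, CellTypeProfile]:
    """Default population profiles for a bone-marrow / peripheral-blood draw.

    ``PC_disease`` equals ``PC_normal`` except on *elevated_markers*, which
    are multiplied by *fold_change*. Abundances are the per-sample defaults
    for the white-blood-cell compartment; the plasma-cell fraction is set per
    sample by :class:`SampleConfig` and the WBC abundances renormalized.
    """
    pc_normal = CellTypeProfile(
        name="PC_normal",
        marker_means={
            **_intercalator_means(),
            "CD138": 20.0,
            "CD38": 15.0,
            "CD56": 10.0,
            "BCMA": 6.0,
            "ICAM3": 5.0,
            "CD221": 5.0,
            "CS1": 6.0,
            "CD74": 4.0,
            "MUM1": 4.0,
            "CD229": 4.0,
            "CD44": 4.0,
            "IGLL5": 3.0,
            "CyclinD1": 3.0,
            "UBA52": 3.0,
            "CD317": 3.0,
            "Blimp1": 3.0,
            "pS6": 2.0,
            "CD27": 3.0,
            "CD81": 3.0,
            "CD117": 1.5,
            "CD28": 1.5,
            "kappa": 5.0,
            "lambda": 5.0,
            "CD45": 1.5,
        },
        nuclear_radius=9.0,
        nuclear_radius_sd=1.0,
        eccentricity=0.45,
        eccentricity_sd=0.12,
        abundance=0.0,
    )
    pc_disease = apply_fold_change(pc_normal, elevated_markers, fold_change)

    t_cell = CellTypeProfile(
        name="T_cell",
        marker_means={
            **_intercalator_means(),
            "CD3": 15.0,
            "CD45": 20.0,
            "CD45RO": 5.0,
            "CD4": 7.0,
            "CD8a": 4.0,
            "CD27": 4.0,
        },
        nuclear_radius=5.5,
        nuclear_radius_sd=0.6,
        eccentricity=0.2,
        eccentricity_sd=0.08,
        abundance=0.16,
    )
    b_cell = CellTypeProfile(
        name="B_cell",
        marker_means={
            **_intercalator_means(),
            "CD20": 14.0,
            "CD45": 18.0,
            "HLA-DR": 8.0,
            "CD81": 4.0,
        },
        nuclear_radius=5.5,
        nuclear_radius_sd=0.6,
        eccentricity=0.2,
        eccentricity_sd=0.08,
        abundance=0.10,
    )
    nk_cell = CellTypeProfile(
        name="NK_cell",
        marker_means={
            **_intercalator_means(),
            "CD56": 12.0,
            "CD45": 18.0,
        },
        nuclear_radius=5.5,
        nuclear_radius_sd=0.6,
        eccentricity=0.2,
        eccentricity_sd=0.08,
        abundance=0.06,
    )
    monocyte = CellTypeProfile(
        name="monocyte",
        marker_means={
            **_intercalator_means(),
            "HLA-DR": 10.0,
            "CD45": 18.0,
            "CD4": 3.0,
            "CD44": 6.0,
        },
        nuclear_radius=6.5,
        nuclear_radius_sd=0.7,
        eccentricity=0.35,
        eccentricity_sd=0.1,
        abundance=0.12,
    )
    other_wbc = CellTypeProfile(
        name="other_WBC",
        marker_means={
            **_intercalator_means(),
            "CD45": 15.0,
        },
        nuclear_radius=5.8,
        nuclear_radius_sd=0.7,
        eccentricity=0.25,
        eccentricity_sd=0.1,
        abundance=0.56,
    )
    profiles = {
        p.name: p
        for p in (pc_normal, pc_disease, t_cell, b_cell, nk_cell, monocyte, other_wbc)
    }
    panel = default_panel()
    for p in profiles.values():
        p.validate_against(panel)
    return profiles


def apply_fold_change(
    profile: CellTypeProfile,
    markers: tuple[str, ...],
    fold_change: float,
) -> CellTypeProfile:
    """Return a ``PC_disease`` profile elevating *markers* by *fold_change*."""
    if fold_change < 0:
        raise ValueError("fold_change must be non-negative")
    means = dict(profile.marker_means)
    for m in markers:
        means[m] = means.get(m, 0.0) * fold_change
    return replace(profile, name="PC_disease", marker_means=means)


@dataclass(frozen=True)
class SampleConfig:
    """One sample of a synthetic cohort."""

    sample_id: str
    condition: str
    n_cells: int = 300
    pc_fraction: float = 0.05
    fold_change: float = DEFAULT_FOLD_CHANGE
    elevated_markers: tuple[str, ...] = DEFAULT_ELEVATED_MARKERS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )
        if not 0 <= self.pc_fraction <= 1:
            raise ValueError("pc_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """A multi-sample synthetic cohort; the seed fixes every random draw.

    The default cohort mirrors a small myeloma-spectrum study: two MGUS and
    one SMM sample (precursor), two NDMM, one RRMM and one PCL sample
    (disease), and one normal donor.
    """

    samples: tuple[SampleConfig, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_cells: int = 300,
        pc_fraction: float = 0.05,
        fold_change: float = DEFAULT_FOLD_CHANGE,
        elevated_markers: tuple[str, ...] = DEFAULT_ELEVATED_MARKERS,
    ) -> "CohortConfig":
        def s(sid: str, cond: str) -> SampleConfig:
            return SampleConfig(
                sample_id=sid,
                condition=cond,
                n_cells=n_cells,
                pc_fraction=pc_fraction,
                fold_change=fold_change,
                elevated_markers=elevated_markers,
            )

        return cls(
            samples=(
                s("MGUS1", "precursor"),
                s("MGUS2", "precursor"),
                s("SMM", "precursor"),
                s("NDMM1", "disease"),
                s("NDMM2", "disease"),
                s("RRMM", "disease"),
                s("PCL", "disease"),
                s("ND", "normal"),
            ),
            seed=seed,
        )
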