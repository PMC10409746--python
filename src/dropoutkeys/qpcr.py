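"""qPCR absolute quantification: raw readouts to normalized abundances.

A qPCR run reports 16S rRNA gene copies per 5 ng of gDNA template. To obtain
the absolute abundance of a strain in the original sample the readout is
scaled by the total extracted gDNA (concentration x elution volume, divided
by the template mass actually loaded), divided by the strain-specific 16S
copy number per genome (yielding genome equivalents), and divided by the
sample volume or mass:

    abundance = copies_per_template * (gdna_conc * elution_volume / template_mass)
                / n_16S / sample_amount

This product/quotient form is the only dimensionally consistent composition
of the four named normalization factors that yields copies (or genome
equivalents) per ml or per g. Detection-limit censoring acts on the raw
copies-per-template scale, before any normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import StrainInfo, ValidationError


@dataclass(frozen=True)
class QPCRReadout:
    """One raw qPCR measurement of one strain in one sample."""

    sample_id: str
    strain_id: str
    copies_per_template: float  # 16S copies per `template_mass` ng gDNA
    gdna_conc: float  # ng/ul of extracted gDNA
    elution_volume: float = 150.0  # ul
    template_mass: float = 5.0  # ng loaded into the reaction
    sample_amount: float = 1.0  # ml (culture) or g (gut content)

    def __post_init__(self) -> None:
        if self.copies_per_template < 0:
            raise ValidationError("copies_per_template must be >= 0")
        if self.gdna_conc < 0:
            raise ValidationError("gdna_conc must be >= 0")
        if self.elution_volume <= 0:
            raise ValidationError("elution_volume must be > 0")
        if self.template_mass <= 0:
            raise ValidationError("template_mass must be > 0")
        if self.sample_amount <= 0:
            raise ValidationError("sample_amount must be > 0")

    @property
    def elution_factor(self) -> float:
        """Total-gDNA scale-up: (ng/ul x ul) / ng template = reactions per extract."""
        return self.gdna_conc * self.elution_volume / self.template_mass


def normalize_qpcr(
    readout: QPCRReadout,
    strain: StrainInfo,
    per_genome: bool = True,
) -> tuple[float, bool]:
    """Convert a raw readout into absolute abundance per ml (or g).

    Returns ``(abundance, censored)``. ``per_genome=True`` (default) divides
    by the strain's 16S copy number, reporting genome equivalents;
    ``per_genome=False`` reports normalized 16S copies instead. The censored
    flag is raised when ``copies_per_template`` is strictly below the
    strain's DTL; a censored result carries abundance 0.
    """
    if readout.strain_id != strain.strain_id:
        raise ValidationError(
            f"readout is for {readout.strain_id!r} but strain info is {strain.strain_id!r}"
        )
    censored = readout.copies_per_template < strain.dtl
    if censored:
        return 0.0, True
    value = readout.copies_per_template * readout.elution_factor / readout.sample_amount
    if per_genome:
        value /= strain.n_16S
    return value, False


def simulate_readout(
    abundance: float,
    strain: StrainInfo,
    sample_id: str = "sim",
    gdna_conc: float = 20.0,
    elution_volume: float = 150.0,
    template_mass: float = 5.0,
    sample_amount: float = 1.0,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    per_genome: bool = True,
) -> QPCRReadout:
    """Inverse of :func:`normalize_qpcr` with optional multiplicative noise.

    With ``noise_sigma`` = 0 the round trip ``normalize_qpcr(simulate_readout(a))``
    recovers ``a`` to machine precision (when above the detection limit).
    Noise is lognormal on the copies scale: ``copies *= exp(N(0, sigma))``,
    emulating well-to-well qPCR measurement variation.
    """
    if abundance < 0:
        raise ValidationError("abundance must be >= 0")
    elution_factor = gdna_conc * elution_volume / template_mass
    copies = abundance * sample_amount / elution_factor
    if per_genome:
        copies *= strain.n_16S
    if noise_sigma > 0:
        if rng is None:
            raise ValidationError("rng is required when noise_sigma > 0")
        copies *= float(np.exp(rng.normal(0.0, noise_sigma)))
    return QPCRReadout(
        sample_id=sample_id,
        strain_id=strain.strain_id,
        copies_per_template=copies,
        gdna_conc=gdna_conc,
        elution_volume=elution_volume,
        template_mass=template_mass,
        sample_amount=sample_amount,
    )
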