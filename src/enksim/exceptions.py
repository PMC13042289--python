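"""Exception types shared across enksim modules."""


class EnksimError(Exception):
    """Base class for all enksim errors."""


class ConfigurationError(EnksimError, ValueError):
    """A parameter or configuration value is outside its allowed range."""


class InvalidGenotypeError(EnksimError, ValueError):
    """A genotype vector has the wrong length or dosages outside {0, 1, 2}."""


class ArchitectureError(EnksimError, ValueError):
    """A fitness component refers to loci outside the genome."""


class DegenerateDataError(EnksimError, ValueError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
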