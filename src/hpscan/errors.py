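"""Exception hierarchy; the CLI maps each class to a distinct exit code."""


class HpScanError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(HpScanError):
    """Invalid configuration (bad parameter values, missing files, mismatched runs)."""

    exit_code = 2


class InputError(HpScanError):
    """Malformed or inconsistent input data (VCF problems, missing samples)."""

    exit_code = 3


class DegenerateDataError(HpScanError):
    """Data too degenerate to analyse (no windows pass the SNP filter, zero variance)."""

    exit_code = 4
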