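"""Exception hierarchy shared across the package."""


class SalsaError(Exception):
    """Base class for all package errors."""


class InputError(SalsaError):
    """A caller-supplied value or file violates a precondition."""


class FormatError(InputError):
    """A parsed file is syntactically or semantically malformed."""


class EmptyStructureError(InputError):
    """A structure source yielded zero usable residues."""


class AlignmentError(SalsaError):
    """A superposition or correspondence step could not be completed."""


class IntegrityError(SalsaError):
    """Cross-references between tables, sites, and structures are inconsistent."""
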