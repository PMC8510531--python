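"""Exception types shared across the pipeline."""


class PatchPigmentError(Exception):
    """Base class for all package-specific errors."""


class InputError(PatchPigmentError, ValueError):
    """Malformed user input (bad hex color, bad table row, bad config)."""


class NoPatchError(PatchPigmentError):
    """No foreground patch survives masking."""


class MaskError(PatchPigmentError):
    """Masking produced an unusable result (e.g. several disjoint patches)."""


class ProfileError(PatchPigmentError):
    """Profiling preconditions violated (degenerate patch, narrow ROI...)."""
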