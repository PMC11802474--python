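"""seqscope: streaming quality control for short- and long-read sequencing data."""

__version__ = "0.1.0"

from .config import QCConfig
from .records import ReadPair, SeqRecord, reverse_complement

__all__ = [
    "QCConfig",
    "SeqRecord",
    "ReadPair",
    "reverse_complement",
    "run_qc",
    "__version__",
]


def run_qc(*args, **kwargs):
    from .report import run_qc as _run_qc

    return _run_qc(*args, **kwargs)
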