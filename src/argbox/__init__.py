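"""argbox: individual-information modelling of ArgR operator (ARG box) sites.

The package builds Schneider-style individual-information models from
curated operator alignments, scores sequences in bits (Ri), discovers
palindromic motifs in probe sets by EM, scans genomes with exact DP
p-values under the published dual filter, classifies tandem-box binding-site
architectures, and generates synthetic benchmarks with planted ground truth.
"""

from . import boxdata, discovery, iimodel, scanner, seqio, synthetic
from .boxdata import (
    ArgBoxRecord,
    BindingSiteArchitecture,
    classify_architecture,
    load_table1,
    select_training_set,
)
from .iimodel import (
    IndividualInformationModel,
    PositionFrequencyMatrix,
    build_model,
    build_model_from_sequences,
    build_pfm,
    consensus,
    load_model,
    ri_score,
    save_model,
    small_sample_correction,
)
from .seqio import GenomicInterval, NucleotideSequence, read_fasta, reverse_complement, write_fasta

__version__ = "0.1.0"


def argbox_model(palindromic: bool = True, zero_count_policy: str = "minus_infinity"):
    """The production ARG box model: the 37 curated training boxes, pooled
    with their reverse complements (the operator is an imperfect palindrome
    bound by a symmetric ArgR oligomer)."""
    from .boxdata import training_sequences

    return build_model_from_sequences(
        training_sequences(), palindromic=palindromic, zero_count_policy=zero_count_policy
    )
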