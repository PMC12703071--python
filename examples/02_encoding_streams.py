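"""3-mer tokenization and the model's two input streams.

Tokenizes a short sequence/structure pair, shows the placeholder-completed
tokens and vocabulary sizes, and assembles a padded feature stream.
"""

import numpy as np

from dicersite import build_vocab, tokenize_3mer
from dicersite.encoding import assemble_stream

seq = "GGCAUUACGU"
struct = "(((....)))"

seq_tokens = tokenize_3mer(seq, "sequence")
struct_tokens = tokenize_3mer(struct, "structure")
print("sequence tokens: ", seq_tokens)
print("structure tokens:", struct_tokens)
# one token per nucleotide: the final two are placeholder-completed

seq_vocab = build_vocab("sequence")
struct_vocab = build_vocab("structure")
print(f"vocabulary sizes: sequence={seq_vocab.size}, structure={struct_vocab.size}")
# 4^3+4^2+4 = 84 and 3^3+3^2+3 = 39; id 0 is reserved for padding

rng = np.random.default_rng(0)
stream = assemble_stream(
    seq_vocab.encode(seq_tokens), struct_vocab.encode(struct_tokens),
    seq_embedding=rng.normal(size=(seq_vocab.size + 1, 32)),
    struct_embedding=rng.normal(size=(struct_vocab.size + 1, 32)),
    pad_to=20)
print(f"stream tensor: {stream.values.shape}, "
      f"valid positions: {int(stream.mask.sum())} of {len(stream.mask)}")
# 64 features per position = 32 sequence + 32 structure dims, plus the
# sinusoidal positional encoding; padded positions are zero and masked out
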