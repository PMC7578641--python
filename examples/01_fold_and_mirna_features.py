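"""Fold a pre-miRNA hairpin and extract its 126-dimension feature vector.

The vector is 10 global hairpin descriptors, 32 structure-triplet counts
(paired/unpaired pattern of three adjacent positions x middle base) and
84 overlapping k-mer counts (4 mono + 16 di + 64 tri).
"""

from seqsymrf import (
    FEATURE_NAMES,
    RnaRecord,
    fold_fallback,
    global_features,
    mirna_vector,
)

record = RnaRecord(id="toy-hairpin", sequence="GGGCGCGCAAAAGCGCGCCCAA")
structure = fold_fallback(record)  # Nussinov max-pairing stand-in for RNAfold

print(f"sequence  {record.sequence}")
print(f"structure {structure.dotbracket}   (mfe proxy {structure.mfe:.1f})")

vector = mirna_vector(record, structure)
print(f"\nfeature vector length: {len(vector)} (should always be 126)\n")

print("global descriptors:")
for name, value in zip(FEATURE_NAMES[:10], vector[:10]):
    print(f"  {name:22s} {value:8.3f}")

# The global block summarises the hairpin's geometry: base pairs and GC
# content measure stem stability, the central loop and bulges its shape,
# tails the unpaired overhangs, and free energy per nucleotide its folding
# strength (here a pair-count proxy from the bundled folder).
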