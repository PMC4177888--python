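"""Local Matching Score basics: raw score, pair score, normalized distance.

The LMS compares proteins through their shared 5-residue words.  Every
window contributes the sum of BLOSUM62 diagonal scores over its residues;
a window counts toward the pair score only when its word occurs verbatim
in the partner sequence.
"""

from kinout import lms_distance, lms_pair, lms_raw

a = "MKTAYIAKQR"
b = "MKTAYWWWWW"   # shares exactly one 5-mer (MKTAY) with a
c = "CCCCCCCCCC"   # shares nothing with a

print(f"raw({a!r})          = {lms_raw(a)}")
print(f"raw({b!r})          = {lms_raw(b)}")
print(f"pair({a!r}, {b!r}) = {lms_pair(a, b)}")
print(f"D(a, b) = {lms_distance(a, b):.4f}   # one shared word -> strictly between 0 and 1")
print(f"D(a, a) = {lms_distance(a, a):.4f}   # identical sequences -> 0")
print(f"D(a, c) = {lms_distance(a, c):.4f}   # no shared word -> 1")
print()
print("The pair score (52) is the shared word MKTAY scored once per direction:")
print("M+K+T+A+Y = 5+5+5+4+7 = 26 from each side.")
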