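-- Distinct peptides between 8 and 30 amino acids in length
-- (30-residue peptides belong to the long partition).
SELECT DISTINCT Sequence
FROM psm
WHERE length(Sequence) >= 8 AND length(Sequence) < 30
ORDER BY Sequence
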