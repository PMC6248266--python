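-- Distinct peptides 30 amino acids or greater in length.
SELECT DISTINCT Sequence
FROM psm
WHERE length(Sequence) >= 30
ORDER BY Sequence
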