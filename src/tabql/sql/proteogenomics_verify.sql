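-- Verified variant PSMs: keep a PSM only when its peptide has no
-- perfect full-length gapless BLAST hit against the known-protein
-- database (pident = 100 AND gapopen = 0 AND alignment length = qlen).
SELECT psm.Spectrum_ID, psm.Sequence, psm.Proteins, psm.Score
FROM psm
WHERE NOT EXISTS (
    SELECT 1
    FROM blast
    WHERE blast.qseqid = psm.Sequence
      AND blast.pident = 100.0
      AND blast.gapopen = 0
      AND blast.length = blast.qlen
)
ORDER BY psm.rowid
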