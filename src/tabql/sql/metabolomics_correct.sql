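-- Two-part mass-error correction. The inner query determines the
-- average relative mass error of features below the mass threshold,
-- matching each feature to its nearest standard within a relative
-- tolerance window. The outer query emits every feature, dividing the
-- mz of below-threshold features by (1 + average relative error);
-- retention time and intensity pass through unchanged.
SELECT
    CASE WHEN f.mz < :threshold
         THEN f.mz / (1.0 + (
              SELECT AVG((f2.mz - s.mass) / s.mass)
              FROM features AS f2
              JOIN standards AS s
                ON ABS(f2.mz - s.mass) / s.mass <= :tolerance
               AND NOT EXISTS (
                   SELECT 1 FROM standards AS s2
                   WHERE ABS(f2.mz - s2.mass) < ABS(f2.mz - s.mass))
              WHERE f2.mz < :threshold))
         ELSE f.mz
    END AS mz,
    f.rt AS rt,
    f.intensity AS intensity
FROM features AS f
ORDER BY f.rowid
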