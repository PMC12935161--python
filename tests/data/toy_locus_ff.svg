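<svg xmlns="http://www.w3.org/2000/svg" width="2280" height="184" viewBox="0 0 2280 184">
<rect width="100%" height="100%" fill="#ffffff"/>
<text x="180" y="30" font-size="12" font-family="sans-serif" text-anchor="start" data-role="title">TOY1</text>
<line x1="180" y1="51" x2="1980" y2="51" stroke="#636363" stroke-width="1" data-role="intron"/>
<rect x="180" y="48.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="480" y="48.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="780" y="48.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1180" y="48.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1580" y="48.2" width="400" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="530" y="44" width="150" height="14" fill="#3182bd" data-role="cds"/>
<rect x="780" y="44" width="300" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1180" y="44" width="300" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1580" y="44" width="150" height="14" fill="#3182bd" data-role="cds"/>
<text x="172" y="54" font-size="9" font-family="sans-serif" text-anchor="end" data-role="lane_label">TOY1.T1</text>
<line x1="180" y1="75" x2="1980" y2="75" stroke="#636363" stroke-width="1" data-role="intron"/>
<rect x="180" y="72.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="780" y="72.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1180" y="72.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1580" y="72.2" width="400" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="830" y="68" width="250" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1180" y="68" width="300" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1580" y="68" width="100" height="14" fill="#3182bd" data-role="cds"/>
<text x="172" y="78" font-size="9" font-family="sans-serif" text-anchor="end" data-role="lane_label">TOY1.T2</text>
<line x1="480" y1="99" x2="1480" y2="99" stroke="#636363" stroke-width="1" data-role="intron"/>
<rect x="480" y="96.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="780" y="96.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1180" y="96.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="530" y="92" width="150" height="14" fill="#3182bd" data-role="cds"/>
<rect x="780" y="92" width="300" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1180" y="92" width="150" height="14" fill="#3182bd" data-role="cds"/>
<text x="172" y="102" font-size="9" font-family="sans-serif" text-anchor="end" data-role="lane_label">TOY1.T3</text>
<line x1="180" y1="123" x2="1980" y2="123" stroke="#636363" stroke-width="1" data-role="intron"/>
<rect x="180" y="120.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="480" y="120.2" width="200" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1180" y="120.2" width="300" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="1580" y="120.2" width="400" height="5.6" fill="#9ecae1" data-role="exon"/>
<rect x="530" y="116" width="150" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1180" y="116" width="300" height="14" fill="#3182bd" data-role="cds"/>
<rect x="1580" y="116" width="50" height="14" fill="#3182bd" data-role="cds"/>
<text x="172" y="126" font-size="9" font-family="sans-serif" text-anchor="end" data-role="lane_label">TOY1.T4</text>
<line x1="180" y1="40" x2="180" y2="134" stroke="#d62728" stroke-width="1" data-role="tss_guide"/>
<line x1="480" y1="40" x2="480" y2="134" stroke="#d62728" stroke-width="1" data-role="tss_guide"/>
<rect x="557" y="60" width="123" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="780" y="60" width="90" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="1077" y="60" width="3" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="1180" y="60" width="210" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="947" y="84" width="133" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="1180" y="84" width="80" height="4" fill="#756bb1" data-role="feature_domain"/>
<rect x="530" y="108" width="60" height="4" fill="#e6550d" data-role="feature_signal_peptide"/>
<text x="2040" y="36" font-size="9" font-family="sans-serif" text-anchor="start" data-role="column_header">biotype</text>
<text x="2040" y="54" font-size="9" font-family="sans-serif" text-anchor="start" data-role="np_categorical">coding</text>
<text x="2040" y="78" font-size="9" font-family="sans-serif" text-anchor="start" data-role="np_categorical">coding</text>
<text x="2040" y="102" font-size="9" font-family="sans-serif" text-anchor="start" data-role="np_categorical">NMD</text>
<text x="2040" y="126" font-size="9" font-family="sans-serif" text-anchor="start" data-role="np_categorical">coding</text>
<text x="2110" y="36" font-size="9" font-family="sans-serif" text-anchor="start" data-role="column_header">expression</text>
<rect x="2110" y="47" width="60" height="8" fill="#636363" data-role="np_continuous"/>
<rect x="2110" y="71" width="29.032" height="8" fill="#636363" data-role="np_continuous"/>
<rect x="2110" y="95" width="30" height="8" fill="#636363" data-role="np_continuous"/>
<rect x="2110" y="119" width="18.387" height="8" fill="#636363" data-role="np_continuous"/>
<text x="2180" y="36" font-size="9" font-family="sans-serif" text-anchor="start" data-role="column_header">uorf</text>
<rect x="2180" y="47" width="8" height="8" fill="#000000" data-role="np_binary"/>
<rect x="2180" y="119" width="8" height="8" fill="#000000" data-role="np_binary"/>
</svg>
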