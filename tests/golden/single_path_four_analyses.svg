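<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="962.00" height="164.00" viewBox="0 0 962.00 164.00">
<rect x="0" y="0" width="962.00" height="164.00" fill="#ffffff"/>
<text x="369.00" y="28.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">analysis_1</text>
<text x="537.00" y="28.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">analysis_2</text>
<text x="705.00" y="28.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">analysis_3</text>
<text x="873.00" y="28.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">analysis_4</text>
<text x="14.00" y="55.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">root process</text>
<line x1="294.00" y1="51.00" x2="948.00" y2="51.00" stroke="#eeeeee" stroke-width="1"/>
<text x="28.00" y="77.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">branch B</text>
<line x1="294.00" y1="73.00" x2="948.00" y2="73.00" stroke="#eeeeee" stroke-width="1"/>
<text x="42.00" y="99.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">join D</text>
<line x1="294.00" y1="95.00" x2="948.00" y2="95.00" stroke="#eeeeee" stroke-width="1"/>
<rect x="330.00" y="88.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="350.25,90.50 345.25,99.50 355.25,99.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<rect x="535.50" y="88.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="537.00,90.50 532.00,99.50 542.00,99.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<rect x="741.00" y="88.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="723.75,90.50 718.75,99.50 728.75,99.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<rect x="946.50" y="88.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="910.50,90.50 905.50,99.50 915.50,99.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<text x="56.00" y="121.50" font-family="Helvetica, Arial, sans-serif" font-size="11.00" class="term-label">leaf E</text>
<line x1="294.00" y1="117.00" x2="948.00" y2="117.00" stroke="#eeeeee" stroke-width="1"/>
<rect x="297.19" y="110.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="303.38,121.50 298.38,112.50 308.38,112.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<rect x="465.19" y="110.00" width="3.00" height="14.00" fill="#d62728" class="fold-bar"/>
<polygon points="471.38,121.50 466.38,112.50 476.38,112.50" fill="#2ca02c" class="odds-ratio-triangle"/>
<rect x="633.19" y="110.00" width="3.00" height="14.00" fill="#9e9e9e" class="fold-bar"/>
<polygon points="639.38,121.50 634.38,112.50 644.38,112.50" fill="#f7b6d2" class="odds-ratio-triangle"/>
<rect x="801.19" y="110.00" width="3.00" height="14.00" fill="#9e9e9e" class="fold-bar"/>
<polygon points="807.38,121.50 802.38,112.50 812.38,112.50" fill="#f7b6d2" class="odds-ratio-triangle"/>
<line x1="294.00" y1="134.00" x2="444.00" y2="134.00" stroke="#333333" stroke-width="1"/>
<line x1="294.00" y1="134.00" x2="294.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="294.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="369.00" y1="134.00" x2="369.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="369.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">4</text>
<line x1="444.00" y1="134.00" x2="444.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="444.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">8</text>
<line x1="462.00" y1="134.00" x2="612.00" y2="134.00" stroke="#333333" stroke-width="1"/>
<line x1="462.00" y1="134.00" x2="462.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="462.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="537.00" y1="134.00" x2="537.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="537.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">4</text>
<line x1="612.00" y1="134.00" x2="612.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="612.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">8</text>
<line x1="630.00" y1="134.00" x2="780.00" y2="134.00" stroke="#333333" stroke-width="1"/>
<line x1="630.00" y1="134.00" x2="630.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="630.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="705.00" y1="134.00" x2="705.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="705.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">4</text>
<line x1="780.00" y1="134.00" x2="780.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="780.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">8</text>
<line x1="798.00" y1="134.00" x2="948.00" y2="134.00" stroke="#333333" stroke-width="1"/>
<line x1="798.00" y1="134.00" x2="798.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="798.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">0</text>
<line x1="873.00" y1="134.00" x2="873.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="873.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">4</text>
<line x1="948.00" y1="134.00" x2="948.00" y2="138.00" stroke="#333333" stroke-width="1"/>
<text x="948.00" y="149.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" text-anchor="middle">8</text>
<text x="294.00" y="161.00" font-family="Helvetica, Arial, sans-serif" font-size="11.00" font-style="italic">fold change</text>
</svg>
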