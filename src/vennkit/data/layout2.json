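{"n":2,"canvas":[700.0,700.0],"curves":{"A":[[430.0,350.0],[429.8,358.34],[429.18,366.66],[428.16,374.94],[426.73,383.17],[424.91,391.31],[422.68,399.35],[420.06,407.27],[417.06,415.06],[413.68,422.68],[409.93,430.14],[405.81,437.4],[401.35,444.45],[396.55,451.27],[391.41,457.85],[385.96,464.17],[380.21,470.21],[374.17,475.96],[367.85,481.41],[361.27,486.55],[354.45,491.35],[347.4,495.81],[340.14,499.93],[332.68,503.68],[325.06,507.06],[317.27,510.06],[309.35,512.68],[301.31,514.91],[293.17,516.73],[284.94,518.16],[276.66,519.18],[268.34,519.8],[260.0,520.0],[251.66,519.8],[243.34,519.18],[235.06,518.16],[226.83,516.73],[218.69,514.91],[210.65,512.68],[202.73,510.06],[194.94,507.06],[187.32,503.68],[179.86,499.93],[172.6,495.81],[165.55,491.35],[158.73,486.55],[152.15,481.41],[145.83,475.96],[139.79,470.21],[134.04,464.17],[128.59,457.85],[123.45,451.27],[118.65,444.45],[114.19,437.4],[110.07,430.14],[106.32,422.68],[102.94,415.06],[99.94,407.27],[97.32,399.35],[95.09,391.31],[93.27,383.17],[91.84,374.94],[90.82,366.66],[90.2,358.34],[90.0,350.0],[90.2,341.66],[90.82,333.34],[91.84,325.06],[93.27,316.83],[95.09,308.69],[97.32,300.65],[99.94,292.73],[102.94,284.94],[106.32,277.32],[110.07,269.86],[114.19,262.6],[118.65,255.55],[123.45,248.73],[128.59,242.15],[134.04,235.83],[139.79,229.79],[145.83,224.04],[152.15,218.59],[158.73,213.45],[165.55,208.65],[172.6,204.19],[179.86,200.07],[187.32,196.32],[194.94,192.94],[202.73,189.94],[210.65,187.32],[218.69,185.09],[226.83,183.27],[235.06,181.84],[243.34,180.82],[251.66,180.2],[260.0,180.0],[268.34,180.2],[276.66,180.82],[284.94,181.84],[293.17,183.27],[301.31,185.09],[309.35,187.32],[317.27,189.94],[325.06,192.94],[332.68,196.32],[340.14,200.07],[347.4,204.19],[354.45,208.65],[361.27,213.45],[367.85,218.59],[374.17,224.04],[380.21,229.79],[385.96,235.83],[391.41,242.15],[396.55,248.73],[401.35,255.55],[405.81,262.6],[409.93,269.86],[413.68,277.32],[417.06,284.94],[420.06,292.73],[422.68,300.65],[424.91,308.69],[426.73,316.83],[428.16,325.06],[429.18,333.34],[429.8,341.66]],"B":[[610.0,350.0],[609.8,358.34],[609.18,366.66],[608.16,374.94],[606.73,383.17],[604.91,391.31],[602.68,399.35],[600.06,407.27],[597.06,415.06],[593.68,422.68],[589.93,430.14],[585.81,437.4],[581.35,444.45],[576.55,451.27],[571.41,457.85],[565.96,464.17],[560.21,470.21],[554.17,475.96],[547.85,481.41],[541.27,486.55],[534.45,491.35],[527.4,495.81],[520.14,499.93],[512.68,503.68],[505.06,507.06],[497.27,510.06],[489.35,512.68],[481.31,514.91],[473.17,516.73],[464.94,518.16],[456.66,519.18],[448.34,519.8],[440.0,520.0],[431.66,519.8],[423.34,519.18],[415.06,518.16],[406.83,516.73],[398.69,514.91],[390.65,512.68],[382.73,510.06],[374.94,507.06],[367.32,503.68],[359.86,499.93],[352.6,495.81],[345.55,491.35],[338.73,486.55],[332.15,481.41],[325.83,475.96],[319.79,470.21],[314.04,464.17],[308.59,457.85],[303.45,451.27],[298.65,444.45],[294.19,437.4],[290.07,430.14],[286.32,422.68],[282.94,415.06],[279.94,407.27],[277.32,399.35],[275.09,391.31],[273.27,383.17],[271.84,374.94],[270.82,366.66],[270.2,358.34],[270.0,350.0],[270.2,341.66],[270.82,333.34],[271.84,325.06],[273.27,316.83],[275.09,308.69],[277.32,300.65],[279.94,292.73],[282.94,284.94],[286.32,277.32],[290.07,269.86],[294.19,262.6],[298.65,255.55],[303.45,248.73],[308.59,242.15],[314.04,235.83],[319.79,229.79],[325.83,224.04],[332.15,218.59],[338.73,213.45],[345.55,208.65],[352.6,204.19],[359.86,200.07],[367.32,196.32],[374.94,192.94],[382.73,189.94],[390.65,187.32],[398.69,185.09],[406.83,183.27],[415.06,181.84],[423.34,180.82],[431.66,180.2],[440.0,180.0],[448.34,180.2],[456.66,180.82],[464.94,181.84],[473.17,183.27],[481.31,185.09],[489.35,187.32],[497.27,189.94],[505.06,192.94],[512.68,196.32],[520.14,200.07],[527.4,204.19],[534.45,208.65],[541.27,213.45],[547.85,218.59],[554.17,224.04],[560.21,229.79],[565.96,235.83],[571.41,242.15],[576.55,248.73],[581.35,255.55],[585.81,262.6],[589.93,269.86],[593.68,277.32],[597.06,284.94],[600.06,292.73],[602.68,300.65],[604.91,308.69],[606.73,316.83],[608.16,325.06],[609.18,333.34],[609.8,341.66]]},"anchors":{"A":[180.1,354.17],"B":[519.9,354.17],"AB":[350.0,354.17]},"name_positions":{"A":[180.1,336.17],"B":[519.9,336.17]}}
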