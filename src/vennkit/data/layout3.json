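{"n":3,"canvas":[700.0,700.0],"curves":{"A":[[520.0,255.0],[519.8,263.34],[519.18,271.66],[518.16,279.94],[516.73,288.17],[514.91,296.31],[512.68,304.35],[510.06,312.27],[507.06,320.06],[503.68,327.68],[499.93,335.14],[495.81,342.4],[491.35,349.45],[486.55,356.27],[481.41,362.85],[475.96,369.17],[470.21,375.21],[464.17,380.96],[457.85,386.41],[451.27,391.55],[444.45,396.35],[437.4,400.81],[430.14,404.93],[422.68,408.68],[415.06,412.06],[407.27,415.06],[399.35,417.68],[391.31,419.91],[383.17,421.73],[374.94,423.16],[366.66,424.18],[358.34,424.8],[350.0,425.0],[341.66,424.8],[333.34,424.18],[325.06,423.16],[316.83,421.73],[308.69,419.91],[300.65,417.68],[292.73,415.06],[284.94,412.06],[277.32,408.68],[269.86,404.93],[262.6,400.81],[255.55,396.35],[248.73,391.55],[242.15,386.41],[235.83,380.96],[229.79,375.21],[224.04,369.17],[218.59,362.85],[213.45,356.27],[208.65,349.45],[204.19,342.4],[200.07,335.14],[196.32,327.68],[192.94,320.06],[189.94,312.27],[187.32,304.35],[185.09,296.31],[183.27,288.17],[181.84,279.94],[180.82,271.66],[180.2,263.34],[180.0,255.0],[180.2,246.66],[180.82,238.34],[181.84,230.06],[183.27,221.83],[185.09,213.69],[187.32,205.65],[189.94,197.73],[192.94,189.94],[196.32,182.32],[200.07,174.86],[204.19,167.6],[208.65,160.55],[213.45,153.73],[218.59,147.15],[224.04,140.83],[229.79,134.79],[235.83,129.04],[242.15,123.59],[248.73,118.45],[255.55,113.65],[262.6,109.19],[269.86,105.07],[277.32,101.32],[284.94,97.94],[292.73,94.94],[300.65,92.32],[308.69,90.09],[316.83,88.27],[325.06,86.84],[333.34,85.82],[341.66,85.2],[350.0,85.0],[358.34,85.2],[366.66,85.82],[374.94,86.84],[383.17,88.27],[391.31,90.09],[399.35,92.32],[407.27,94.94],[415.06,97.94],[422.68,101.32],[430.14,105.07],[437.4,109.19],[444.45,113.65],[451.27,118.45],[457.85,123.59],[464.17,129.04],[470.21,134.79],[475.96,140.83],[481.41,147.15],[486.55,153.73],[491.35,160.55],[495.81,167.6],[499.93,174.86],[503.68,182.32],[507.06,189.94],[510.06,197.73],[512.68,205.65],[514.91,213.69],[516.73,221.83],[518.16,230.06],[519.18,238.34],[519.8,246.66]],"B":[[602.27,397.5],[602.07,405.84],[601.45,414.16],[600.43,422.44],[599.01,430.67],[597.18,438.81],[594.95,446.85],[592.33,454.77],[589.33,462.56],[585.95,470.18],[582.2,477.64],[578.09,484.9],[573.62,491.95],[568.82,498.77],[563.68,505.35],[558.23,511.67],[552.48,517.71],[546.44,523.46],[540.12,528.91],[533.54,534.05],[526.72,538.85],[519.67,543.31],[512.41,547.43],[504.96,551.18],[497.33,554.56],[489.54,557.56],[481.62,560.18],[473.58,562.41],[465.44,564.23],[457.22,565.66],[448.94,566.68],[440.61,567.3],[432.27,567.5],[423.93,567.3],[415.61,566.68],[407.33,565.66],[399.11,564.23],[390.97,562.41],[382.92,560.18],[375.0,557.56],[367.22,554.56],[359.59,551.18],[352.13,547.43],[344.87,543.31],[337.83,538.85],[331.0,534.05],[324.43,528.91],[318.11,523.46],[312.06,517.71],[306.31,511.67],[300.86,505.35],[295.73,498.77],[290.92,491.95],[286.46,484.9],[282.35,477.64],[278.59,470.18],[275.21,462.56],[272.21,454.77],[269.59,446.85],[267.37,438.81],[265.54,430.67],[264.11,422.44],[263.09,414.16],[262.48,405.84],[262.27,397.5],[262.48,389.16],[263.09,380.84],[264.11,372.56],[265.54,364.33],[267.37,356.19],[269.59,348.15],[272.21,340.23],[275.21,332.44],[278.59,324.82],[282.35,317.36],[286.46,310.1],[290.92,303.05],[295.73,296.23],[300.86,289.65],[306.31,283.33],[312.06,277.29],[318.11,271.54],[324.43,266.09],[331.0,260.95],[337.83,256.15],[344.87,251.69],[352.13,247.57],[359.59,243.82],[367.22,240.44],[375.0,237.44],[382.92,234.82],[390.97,232.59],[399.11,230.77],[407.33,229.34],[415.61,228.32],[423.93,227.7],[432.27,227.5],[440.61,227.7],[448.94,228.32],[457.22,229.34],[465.44,230.77],[473.58,232.59],[481.62,234.82],[489.54,237.44],[497.33,240.44],[504.96,243.82],[512.41,247.57],[519.67,251.69],[526.72,256.15],[533.54,260.95],[540.12,266.09],[546.44,271.54],[552.48,277.29],[558.23,283.33],[563.68,289.65],[568.82,296.23],[573.62,303.05],[578.09,310.1],[582.2,317.36],[585.95,324.82],[589.33,332.44],[592.33,340.23],[594.95,348.15],[597.18,356.19],[599.01,364.33],[600.43,372.56],[601.45,380.84],[602.07,389.16]],"C":[[437.73,397.5],[437.52,405.84],[436.91,414.16],[435.89,422.44],[434.46,430.67],[432.63,438.81],[430.41,446.85],[427.79,454.77],[424.79,462.56],[421.41,470.18],[417.65,477.64],[413.54,484.9],[409.08,491.95],[404.27,498.77],[399.14,505.35],[393.69,511.67],[387.94,517.71],[381.89,523.46],[375.57,528.91],[369.0,534.05],[362.17,538.85],[355.13,543.31],[347.87,547.43],[340.41,551.18],[332.78,554.56],[325.0,557.56],[317.08,560.18],[309.03,562.41],[300.89,564.23],[292.67,565.66],[284.39,566.68],[276.07,567.3],[267.73,567.5],[259.39,567.3],[251.06,566.68],[242.78,565.66],[234.56,564.23],[226.42,562.41],[218.38,560.18],[210.46,557.56],[202.67,554.56],[195.04,551.18],[187.59,547.43],[180.33,543.31],[173.28,538.85],[166.46,534.05],[159.88,528.91],[153.56,523.46],[147.52,517.71],[141.77,511.67],[136.32,505.35],[131.18,498.77],[126.38,491.95],[121.91,484.9],[117.8,477.64],[114.05,470.18],[110.67,462.56],[107.67,454.77],[105.05,446.85],[102.82,438.81],[100.99,430.67],[99.57,422.44],[98.55,414.16],[97.93,405.84],[97.73,397.5],[97.93,389.16],[98.55,380.84],[99.57,372.56],[100.99,364.33],[102.82,356.19],[105.05,348.15],[107.67,340.23],[110.67,332.44],[114.05,324.82],[117.8,317.36],[121.91,310.1],[126.38,303.05],[131.18,296.23],[136.32,289.65],[141.77,283.33],[147.52,277.29],[153.56,271.54],[159.88,266.09],[166.46,260.95],[173.28,256.15],[180.33,251.69],[187.59,247.57],[195.04,243.82],[202.67,240.44],[210.46,237.44],[218.38,234.82],[226.42,232.59],[234.56,230.77],[242.78,229.34],[251.06,228.32],[259.39,227.7],[267.73,227.5],[276.07,227.7],[284.39,228.32],[292.67,229.34],[300.89,230.77],[309.03,232.59],[317.08,234.82],[325.0,237.44],[332.78,240.44],[340.41,243.82],[347.87,247.57],[355.13,251.69],[362.17,256.15],[369.0,260.95],[375.57,266.09],[381.89,271.54],[387.94,277.29],[393.69,283.33],[399.14,289.65],[404.27,296.23],[409.08,303.05],[413.54,310.1],[417.65,317.36],[421.41,324.82],[424.79,332.44],[427.79,340.23],[430.41,348.15],[432.63,356.19],[434.46,364.33],[435.89,372.56],[436.91,380.84],[437.52,389.16]]},"anchors":{"A":[350.0,171.23],"B":[519.49,410.0],"C":[180.51,410.0],"AB":[462.64,314.81],"AC":[237.36,314.81],"BC":[350.0,473.91],"ABC":[350.0,336.34]},"name_positions":{"A":[350.0,153.23],"B":[519.49,392.0],"C":[180.51,392.0]}}
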